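# Methods

## Problem and models

CT numbers (Hounsfield units, HU) are calibrated so that water reads 0 and
air −1000 at every tube potential, but tissues whose effective atomic number
differs from water shift with the spectrum: bone mineral attenuates
disproportionately at soft spectra, adipose tissue the opposite way.  A
phantom material that matches a tissue at 120 kV can therefore mismatch it
badly at 70 kV.  The package models the kV dependence of tissue CT numbers
over 70–140 kV from a single reference measurement at 120 kV:

- **Bone** — multiplicative: `HU(kV) = k(kV) · HU(120)`, with
  `k(kV) = a·kV⁴ + b·kV³ + c·kV² + d·kV + e`.  The multiplicative form
  reflects the mineral-content scaling of attenuation: harder bone both
  attenuates more and swings more with the spectrum.
- **Adipose** — additive: `HU(kV) = HU(120) + Δ(kV)`, with
  `Δ(kV) = α·kV² + β·kV + γ`.  Fat of any density shifts by roughly the same
  absolute offset, negative at soft spectra.
- **Soft tissue** — constant (water-equivalent mass energy attenuation);
  represented by a user-supplied constant, default 65 HU (mid muscle range).

The packaged coefficient set (`reference_models()`) was fitted to fresh
bovine/porcine specimen scans at 70/80/100/120/140 kV.  The coefficients are
carried verbatim: `k(120) = 0.9962`, not exactly 1, and `Δ(120) = −0.009 HU`.
We deliberately do not renormalise — the printed downstream tables derive
from these exact values — and `rebase_reference()` provides explicit
re-anchoring (divide the quartic by `k(kV₀)`, shift γ by `−Δ(kV₀)`) whenever
exact self-consistency at an anchor is wanted.

Numerically, polynomials are evaluated in `kV/100` (kV⁴ ≈ 4·10⁸ at 140 kV
would otherwise dominate conditioning); coefficients are stored and reported
on the natural scale.  Tube potentials outside [70, 140] kV trigger a warning
but never an error: the polynomial extrapolates smoothly, the validation does
not extend there.  Predictions with tin-filtered or otherwise non-standard
spectra are out of scope; the coefficients are spectrum-specific.

## Fitting

Each measured sample contributes an HU-vs-kV series anchored at its own
measured 120-kV value.  Coefficients minimise the pooled sum of squared
residuals over all series and tube potentials (equally weighted per point;
optional 1/σ² weighting when per-point SDs exist; an L1 objective is
available but non-default since a smooth least-squares reading of the
source procedure is the most defensible one).  Both fits are linear in
their coefficients.  The adipose fit is solved in closed form.  The bone fit
runs through `scipy.optimize.least_squares` with the analytic Jacobian on
the kV/100 scale from a configurable start point (default: the
energy-independent model k ≡ 1, convergence at 1e−10 relative change),
which makes start-point independence and robust-loss variants trivial; a
bone fit needs ≥ 5 distinct tube potentials, an adipose fit ≥ 3, else an
underdetermined-fit error is raised.

**Anchoring subtlety.** The generator applies the models verbatim, so a
synthetic series' measured 120-kV value is `k(120)·hu_ref` with
`k(120) = 0.9962`.  An anchored fit of such data exactly recovers the
*re-anchored* curves (`k/k(120)`, `Δ − Δ(120)`), not the raw coefficients —
a 0.38 % difference in k.  Recovery tests therefore compare against
`rebase_reference(model, 120)`; predictions of measured values agree
identically either way.

## Material matching by controlled density reduction

Underfilling an FDM print scales its density by the filling ratio
`f = ρ′/ρ` while preserving the mass attenuation coefficient, hence
`HU(ρ′) = f·(HU(ρ) + 1000) − 1000`.  Solving for f matches any tissue target
not exceeding the material's own CT number at the reference kV:
`f = (HU_target + 1000)/(HU_material + 1000)`; targets requiring f > 1 are
infeasible (no "overfilling"), resins are never underfilled (f fixed at 1).
Ratios are reported both at full precision and rounded to one decimal
percent; downstream predictions use full precision to avoid compounding
rounding.

Materials are characterised by their 120-kV CT number plus per-kV offsets to
the equal-CT-number tissue curve (zero at 120 kV by construction).  The
full-density per-kV CT number is reconstructed by inverting that definition:
`HU_mat(kV) = tissue_model(hu_mat_ref, kV) + offset(kV)`.  At the reference
kV the tissue value is the anchor CT number itself (the offset convention
fixes Δ-to-tissue ≡ 0 there, absorbing the model's k(120) ≠ 1).  Residual
tables (`delta_table`) then list, per kV, the difference between the
underfilled material and the tissue model at the target — the quantities
needed to correct measured phantom contrasts back to tissue-equivalent
contrasts (`correct_contrast`).  `rank_materials` scores candidates by the
worst-case |ΔHU| over the kV grid; materials that are infeasible, lack
per-kV data, or were characterised against a different tissue's curve are
excluded with a logged reason — offsets defined against the bone curve
cannot be re-based onto the adipose curve.

## Segmentation pipeline

All segmentation happens on the reference (120 kV) volume and the resulting
labels are applied unchanged to the co-registered volumes at other
potentials, so every segment's statistics cover the same voxel set at every
kV (counts are invariant by construction).  Registration itself is out of
scope; volume sets must arrive aligned, as the synthetic generator produces
them.  Defaults follow the extraction procedure the models were built from:
bone surface at ≥ 300 HU, cortical compartment at ≥ 900 HU, marrow boundary
at the cortical/marrow mean midpoint, adipose within [−200, −20] HU (the
lower bound is ours, to exclude air; the human-convention window [−140, −30]
is a parameter choice away).  Bone voxels are stratified into half-open
200-HU bins from −50 HU (centres 50, 250, … 1850) plus an open top bin
[1950, ∞).  Edge ownership (a value on a lower edge belongs to the higher
bin) is a convention the source phrasing does not fix; half-open intervals
make it deterministic.  Segment SDs are population SDs — voxel counts are
large and the distinction is immaterial.  Manual contour correction is
replaced by an optional largest-connected-component cleanup and
user-supplied exclusion via the mask argument.

## Synthetic data

Real specimen scans are not redistributable, so the generators produce data
with the structure the analysis assumes: series specs draw reference CT
numbers uniformly from a range and apply the models plus independent
Gaussian noise at every grid point (including the reference — a real
measurement is noisy there too); phantom specs paint geometric regions
(boxes, spheres, cylinders, shells) over a water background, per kV, with
optional Gaussian blur (FWHM in mm) emulating partial-volume mixing, then
voxelwise Gaussian noise.  Everything is bit-reproducible from an integer
seed.  What this does *not* emulate: beam hardening, correlated
reconstruction noise, registration error, anatomical texture.  Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated statistical model, not robustness to scanner physics.

Default study conditions: series fits use 40 bone series over 350–1536 HU at
10 HU noise (the span of whole-to-cortical bone anchors) and 20 adipose
series over −100…−40 HU at 5 HU noise; phantoms default to a 64³ grid at
1 mm spacing, which keeps the full pipeline at sub-second runtimes while
every density bin holds thousands of voxels.  The default phantom's bone
anchors (451.7, 853.2, 1254.7, 1656.3 HU) are chosen so the 120-kV voxel
values land exactly on density-bin centres: each region maps to one bin,
≥ 10σ from every bin edge at the default noise, making per-bin means
effectively free of threshold-selection bias.

## Verification summary

The test suite checks, among others: polynomial evaluation against
independent term-by-term and Horner oracles (1000+ random coefficient sets
via hypothesis); exact noiseless interpolation and stochastic coefficient
recovery; closed-form vs iterative equality for the adipose fit; exact
round-trip of the filling-ratio/density-reduction pair; reproduction of all
published filling ratios (one-decimal exact) and residual ΔHU tables
(±5 HU, the budget for published rounding); and full pipeline recovery on
synthetic phantoms (exact at zero noise, within 3σ/√n at 10 HU noise).
`scripts/acceptance.py` recomputes the headline filling ratios from the
packaged library at run time.

## Known limitations

- Coefficients are specific to the characterised scanner spectra; other
  scanners, kernels or added filtration require refitting.
- Material offsets are tabulated only at 70/80/100/140 kV; intermediate
  potentials would need interpolation, which is deliberately not provided.
- The adipose library is thin: only HIPS carries a full characterisation;
  polyamide/ABS/ASA appear with published ratios but without measured
  reference CT numbers, so their plans cannot be recomputed from first
  principles.
- Printability constraints (minimum practical infill, TPU handling, resin
  rigidity) are advisory flags, not a process model.
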