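"""Matching 3D-printing materials to tissue targets by controlled density reduction.

An FDM filament printed with deliberately reduced density ("underfilling")
keeps its mass attenuation coefficient while scaling (HU + 1000)
proportionally to the filling ratio f = rho'/rho:

    HU(rho') = f * (HU(rho) + 1000) - 1000

Solving this for f lets a material that is at least as attenuating as a
tissue target match the target exactly at the reference tube potential.
Because the material's *energy dependence* generally differs from the
tissue's, a residual mismatch delta-HU remains at other kV; this module
tabulates those residuals (per kV) so that phantom contrasts measured at any
tube potential can be corrected back to tissue-equivalent contrasts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import (
    InfeasibleTargetError,
    InsufficientMaterialDataError,
    InvalidInputError,
    MissingGridPointError,
)
from .models import (
    AdiposeDeltaModel,
    BoneEnergyModel,
    SoftTissueModel,
    TissueClass,
    TissueTarget,
    predict_hu,
)

__all__ = [
    "MaterialRecord",
    "FillPlan",
    "reduced_density_hu",
    "filling_ratio_for_target",
    "material_hu_at",
    "delta_table",
    "rank_materials",
    "correct_contrast",
    "read_material_library_csv",
    "write_fill_plans_csv",
]

logger = logging.getLogger(__name__)

TissueCurveModel = Union[BoneEnergyModel, AdiposeDeltaModel, SoftTissueModel]

DEFAULT_KV_GRID: tuple[float, ...] = (70.0, 80.0, 100.0, 120.0, 140.0)


@dataclass(frozen=True)
class MaterialRecord:
    """A printing material's CT attenuation characterisation.

    ``hu_ref`` is the CT number of the solidly printed material at
    ``reference_kv``.  ``delta_to_tissue`` maps tube potential to the
    material's HU difference versus the tissue model evaluated at the *same*
    reference CT number — the standard way these characterisations are
    published, with 0 at the reference kV by construction.  Resins cannot be
    underfilled (``underfillable=False``).
    """

    name: str
    material_class: str  # "filament" | "resin"
    hu_ref: float
    delta_to_tissue: Optional[dict[float, float]] = None
    reference_kv: float = 120.0
    underfillable: bool = True
    tissue_substituted: Optional[str] = None  # advisory: "bone" | "fat"
    notes: str = ""

    def __post_init__(self) -> None:
        if self.material_class not in ("filament", "resin"):
            raise InvalidInputError(
                f"material_class must be 'filament' or 'resin', got {self.material_class!r}")
        if not np.isfinite(self.hu_ref) or self.hu_ref <= -1000:
            raise InvalidInputError(f"{self.name}: hu_ref must be finite and > -1000 HU")
        if self.delta_to_tissue is not None:
            d = {float(k): float(v) for k, v in self.delta_to_tissue.items()}
            d.setdefault(float(self.reference_kv), 0.0)
            if abs(d[float(self.reference_kv)]) > 1e-9:
                raise InvalidInputError(
                    f"{self.name}: delta_to_tissue must be 0 at the reference kV")
            object.__setattr__(self, "delta_to_tissue", d)


@dataclass(frozen=True)
class FillPlan:
    """A density-reduction plan matching one material to one tissue target.

    ``filling_ratio`` is rho'/rho in (0, 1]; ``predicted_hu`` maps kV to the
    CT number of the underfilled print; ``delta_hu`` maps kV to the residual
    difference versus the tissue model (zero at the reference kV up to
    rounding of the ratio).
    """

    material: MaterialRecord
    tissue_target: TissueTarget
    filling_ratio: float
    predicted_hu: dict[float, float]
    delta_hu: dict[float, float]

    def __post_init__(self) -> None:
        if not 0 < self.filling_ratio <= 1 + 1e-12:
            raise InvalidInputError(
                f"filling ratio must be in (0, 1], got {self.filling_ratio}")

    @property
    def filling_percent(self) -> float:
        """Filling ratio as a percentage rounded to one decimal (display convention)."""
        return round(self.filling_ratio * 100, 1)


def reduced_density_hu(hu_full: float, f: float):
    """CT number of a material printed at filling ratio ``f`` of full density.

    ``HU(rho') = f * (HU(rho) + 1000) - 1000``; strictly increasing in both
    arguments.  Accepts scalars or arrays in ``hu_full``.
    """
    arr = np.asarray(hu_full, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= -1000):
        raise InvalidInputError(f"hu_full must be finite and > -1000 HU, got {hu_full!r}")
    if not np.isfinite(f) or f <= 0:
        raise InvalidInputError(f"filling ratio must be positive, got {f!r}")
    out = f * (arr + 1000.0) - 1000.0
    return float(out) if out.ndim == 0 else out


def filling_ratio_for_target(hu_material_ref: float, hu_target_ref: float) -> float:
    """Filling ratio making a material match a tissue CT number at the reference kV.

    ``f = (HU_target + 1000) / (HU_material + 1000)``; requires the material
    to be at least as attenuating as the target (otherwise f would exceed 1,
    physically impossible with underfilling).
    """
    for name, v in (("hu_material_ref", hu_material_ref), ("hu_target_ref", hu_target_ref)):
        if not np.isfinite(v) or v <= -1000:
            raise InvalidInputError(f"{name} must be finite and > -1000 HU, got {v!r}")
    f = (hu_target_ref + 1000.0) / (hu_material_ref + 1000.0)
    if f > 1 + 1e-12:
        raise InfeasibleTargetError(
            f"target {hu_target_ref:g} HU exceeds material {hu_material_ref:g} HU: "
            f"required filling ratio {f:.4f} > 1")
    return min(f, 1.0)


def material_hu_at(material: MaterialRecord, kv: float,
                   tissue_model: TissueCurveModel) -> float:
    """Full-density CT number of a material at tube potential ``kv``.

    Reconstructed from the published characterisation: the tissue-model
    prediction at the material's own reference CT number, plus the material's
    tabulated offset to that tissue curve.  This exactly inverts the
    definition of the offset table.
    """
    if abs(kv - material.reference_kv) <= 1e-9:
        return material.hu_ref
    if material.delta_to_tissue is None or float(kv) not in material.delta_to_tissue:
        raise InsufficientMaterialDataError(
            f"{material.name}: no per-kV attenuation data at {kv:g} kV")
    return predict_hu(tissue_model, material.hu_ref, kv) + material.delta_to_tissue[float(kv)]


def delta_table(
    material: MaterialRecord,
    f: float,
    tissue_model: TissueCurveModel,
    tissue_target: TissueTarget,
    kv_grid: Sequence[float] = DEFAULT_KV_GRID,
) -> FillPlan:
    """Per-kV CT numbers and residual offsets of an underfilled material vs a tissue.

    For each kV: ``predicted = f * (HU_material(kV) + 1000) - 1000`` and
    ``delta = predicted - tissue prediction at the target's reference CT
    number``.  When ``f`` solves the target at the reference kV, delta is
    zero there by construction.
    """
    predicted: dict[float, float] = {}
    deltas: dict[float, float] = {}
    for kv in kv_grid:
        hu_m = material_hu_at(material, kv, tissue_model)
        pred = reduced_density_hu(hu_m, f)
        # At the reference kV the tissue value IS the anchor CT number by
        # definition (the offset convention fixes delta(ref) = 0 identically,
        # absorbing the fitted model's k(ref) = 0.9962 self-inconsistency).
        if abs(float(kv) - tissue_target.reference_kv) <= 1e-9:
            tissue = tissue_target.hu_ref
        else:
            tissue = predict_hu(tissue_model, tissue_target.hu_ref, kv)
        predicted[float(kv)] = pred
        deltas[float(kv)] = pred - tissue
    return FillPlan(material=material, tissue_target=tissue_target,
                    filling_ratio=float(f), predicted_hu=predicted, delta_hu=deltas)


def rank_materials(
    materials: Sequence[MaterialRecord],
    tissue_model: TissueCurveModel,
    tissue_target: TissueTarget,
    kv_grid: Sequence[float] = DEFAULT_KV_GRID,
) -> list[tuple[MaterialRecord, FillPlan, float]]:
    """Rank candidate materials for a tissue target by worst-case spectral mismatch.

    The filling ratio is solved per material (resins, which cannot be
    underfilled, are evaluated at f = 1 and then carry their reference-kV
    mismatch in the score); the score is ``max over the kV grid of
    |delta_hu|`` and materials are returned ascending.  Materials that are
    infeasible (less attenuating than the target) or lack per-kV data are
    excluded with a logged reason.
    """
    class_of = {"bone": TissueClass.BONE, "fat": TissueClass.ADIPOSE,
                "adipose": TissueClass.ADIPOSE, "soft": TissueClass.SOFT}
    ranked = []
    for mat in materials:
        # a material's per-kV offsets are defined against the tissue curve it
        # was characterised for; reconstructing against a different tissue
        # model would be meaningless
        if (mat.tissue_substituted is not None
                and class_of.get(mat.tissue_substituted) is not tissue_target.tissue_class):
            logger.info("excluding %s: characterised against %s, target is %s",
                        mat.name, mat.tissue_substituted,
                        tissue_target.tissue_class.value)
            continue
        try:
            if mat.underfillable:
                f = filling_ratio_for_target(mat.hu_ref, tissue_target.hu_ref)
            else:
                f = 1.0
            plan = delta_table(mat, f, tissue_model, tissue_target, kv_grid)
        except (InfeasibleTargetError, InsufficientMaterialDataError) as exc:
            logger.info("excluding %s: %s", mat.name, exc)
            continue
        score = max(abs(v) for v in plan.delta_hu.values())
        ranked.append((mat, plan, score))
    if not ranked:
        warnings.warn(
            f"no feasible material for target {tissue_target.hu_ref:g} HU "
            f"({tissue_target.tissue_class.value})", UserWarning, stacklevel=2)
    ranked.sort(key=lambda t: (t[2], t[0].name))
    return ranked


def correct_contrast(measured_contrast: float, plan_a: FillPlan, plan_b: FillPlan,
                     kv: float) -> float:
    """Convert a phantom contrast measured at ``kv`` to the tissue-equivalent contrast.

    Subtracts the plans' residual-offset difference:
    ``contrast - (delta_a(kV) - delta_b(kV))``.
    """
    key = float(kv)
    for plan, label in ((plan_a, "a"), (plan_b, "b")):
        if key not in plan.delta_hu:
            raise MissingGridPointError(
                f"plan {label} ({plan.material.name}) has no entry at {kv:g} kV")
    return measured_contrast - (plan_a.delta_hu[key] - plan_b.delta_hu[key])


# --- CSV interchange --------------------------------------------------------

LIBRARY_COLUMNS = ["name", "material_class", "tissue", "hu_ref",
                   "delta_70", "delta_80", "delta_100", "delta_140",
                   "underfillable", "polymer", "product"]


def read_material_library_csv(path: str | Path) -> list[MaterialRecord]:
    """Read a material library CSV (see :data:`LIBRARY_COLUMNS`).

    Rows without ``hu_ref`` (uncharacterised materials listed for metadata
    only) are skipped; rows without delta columns get ``delta_to_tissue=None``.
    """
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        if pd.isna(row.get("hu_ref")):
            continue
        deltas = None
        cols = [c for c in df.columns if c.startswith("delta_")]
        if cols and not any(pd.isna(row[c]) for c in cols):
            deltas = {float(c.split("_")[1]): float(row[c]) for c in cols}
        out.append(MaterialRecord(
            name=str(row["name"]),
            material_class=str(row["material_class"]),
            hu_ref=float(row["hu_ref"]),
            delta_to_tissue=deltas,
            underfillable=bool(row.get("underfillable", True)),
            tissue_substituted=None if pd.isna(row.get("tissue")) else str(row["tissue"]),
            notes="" if pd.isna(row.get("notes", None)) else str(row.get("notes", "")),
        ))
    return out


def write_fill_plans_csv(
    plans: Sequence[tuple[MaterialRecord, FillPlan, float]] | Sequence[FillPlan],
    path: str | Path,
) -> None:
    """One row per (material, kV): predicted HU, residual delta-HU, ratio, score."""
    rows = []
    for item in plans:
        if isinstance(item, FillPlan):
            mat, plan, score = item.material, item, max(abs(v) for v in item.delta_hu.values())
        else:
            mat, plan, score = item
        for kv in sorted(plan.predicted_hu):
            rows.append({
                "material": mat.name,
                "target_hu": plan.tissue_target.hu_ref,
                "tissue_class": plan.tissue_target.tissue_class.value,
                "filling_ratio": plan.filling_ratio,
                "filling_percent": plan.filling_percent,
                "kv": kv,
                "predicted_hu": round(plan.predicted_hu[kv], 2),
                "delta_hu": round(plan.delta_hu[kv], 2),
                "score_max_abs_delta": round(score, 2),
            })
    pd.DataFrame(rows).to_csv(path, index=False)
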