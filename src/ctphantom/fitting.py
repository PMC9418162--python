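"""Least-squares estimation of the tissue energy-dependence coefficients.

Each measured sample contributes one HU-vs-kV series anchored at its own
reference-kV (120 kV) measurement.  The bone fit finds the quartic k(kV)
minimising ``sum_s sum_kv (k(kV) * HU_s(ref) - HU_s(kV))^2`` over all series
jointly; the adipose fit finds the quadratic delta(kV) minimising
``sum_s sum_kv (HU_s(ref) + delta(kV) - HU_s(kV))^2``.  Both problems are
linear in their coefficients; the bone fit is nevertheless run through a
smooth iterative least-squares solver (with analytic Jacobian, on the kV/100
scale) so that arbitrary start points and robust-loss variants share one code
path, while the adipose fit is solved in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from .exceptions import ConfigurationError, InvalidInputError, UnderdeterminedFitError
from .models import (
    KV_SCALE,
    AdiposeDeltaModel,
    BoneEnergyModel,
    SoftTissueModel,
    TissueClass,
    TissueModel,
)

__all__ = [
    "HUMeasurementSeries",
    "FitResult",
    "fit_bone_model",
    "fit_adipose_model",
    "goodness_of_fit",
    "read_series_csv",
    "write_series_csv",
    "write_residuals_csv",
]

#: Relative sse-change convergence tolerance for the iterative bone fit.
FTOL = 1e-10


@dataclass(frozen=True)
class HUMeasurementSeries:
    """One sample's mean CT numbers across tube potentials.

    ``points`` holds (kv, hu_mean, hu_sd, n_voxels) tuples; hu_sd and
    n_voxels may be None when the source table lacks them.
    """

    sample_id: str
    tissue_class: TissueClass
    points: tuple[tuple[float, float, Optional[float], Optional[int]], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissue_class", TissueClass(self.tissue_class))
        pts = tuple(
            (float(kv), float(hu), None if sd is None else float(sd), None if n is None else int(n))
            for kv, hu, sd, n in (
                p if len(p) == 4 else (*p, None, None)[:4] for p in self.points
            )
        )
        object.__setattr__(self, "points", pts)
        kvs = [p[0] for p in pts]
        if len(pts) < 2:
            raise InvalidInputError(f"series {self.sample_id!r}: needs at least 2 points")
        if len(set(kvs)) != len(kvs):
            raise InvalidInputError(f"series {self.sample_id!r}: duplicate kV values")
        if not all(math.isfinite(p[0]) and math.isfinite(p[1]) for p in pts):
            raise InvalidInputError(f"series {self.sample_id!r}: non-finite kv/hu")

    @property
    def kv(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def hu_mean(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def hu_at(self, kv: float, tol: float = 1e-6) -> float:
        """Measured mean HU at ``kv`` (exact grid point)."""
        for p in self.points:
            if abs(p[0] - kv) <= tol:
                return p[1]
        raise ConfigurationError(
            f"series {self.sample_id!r} has no measurement at {kv:g} kV "
            "(required as the anchoring reference)"
        )

    @classmethod
    def from_arrays(cls, sample_id, tissue_class, kv, hu_mean, hu_sd=None, n_voxels=None):
        n = len(kv)
        sd = [None] * n if hu_sd is None else list(hu_sd)
        nv = [None] * n if n_voxels is None else list(n_voxels)
        return cls(sample_id, tissue_class, tuple(zip(kv, hu_mean, sd, nv)))


@dataclass
class FitResult:
    """Outcome of a model fit or residual evaluation.

    sse is the sum of squared residuals in HU^2; rmse = sqrt(sse / n_points)
    (NaN when n_points is 0, flagged by ``rmse_defined``).
    """

    model: Optional[TissueModel]
    sse: float
    rmse: float
    per_series_residuals: dict[str, list[tuple[float, float]]]
    n_points: int
    converged: bool
    message: str = ""

    @property
    def rmse_defined(self) -> bool:
        return self.n_points > 0


def _collect(series: Sequence[HUMeasurementSeries], tissue_class: TissueClass,
             reference_kv: float, weighted: bool):
    """Stack all points into flat arrays (kv, hu, anchor hu_ref, weight, ids)."""
    if not series:
        return (np.empty(0),) * 4 + ([],)
    kvs, hus, refs, wts, ids = [], [], [], [], []
    for s in series:
        if s.tissue_class is not tissue_class:
            raise ConfigurationError(
                f"series {s.sample_id!r} has tissue_class {s.tissue_class.value}, "
                f"expected {tissue_class.value}"
            )
        ref = s.hu_at(reference_kv)
        for kv, hu, sd, _n in s.points:
            kvs.append(kv)
            hus.append(hu)
            refs.append(ref)
            if weighted:
                if sd is None or sd <= 0:
                    raise InvalidInputError(
                        f"series {s.sample_id!r}: inverse-variance weighting "
                        "requires positive hu_sd on every point"
                    )
                wts.append(1.0 / sd)
            else:
                wts.append(1.0)
            ids.append(s.sample_id)
    return (np.array(kvs), np.array(hus), np.array(refs), np.array(wts), ids)


def _split_residuals(ids, kvs, res) -> dict[str, list[tuple[float, float]]]:
    out: dict[str, list[tuple[float, float]]] = {}
    for sid, kv, r in zip(ids, kvs, res):
        out.setdefault(sid, []).append((float(kv), float(r)))
    return out


def fit_bone_model(
    series: Sequence[HUMeasurementSeries],
    reference_kv: float = 120.0,
    *,
    x0: Optional[Sequence[float]] = None,
    loss: str = "l2",
    weighted: bool = False,
) -> FitResult:
    """Fit the quartic bone multiplier k(kV) to anchored multi-sample series.

    Each series is anchored at its measured HU(reference_kv); the five
    coefficients minimise the pooled squared residuals (all points equally
    weighted unless ``weighted``, which applies 1/sd weights).  ``loss="l1"``
    minimises the sum of absolute residuals instead (non-default).

    ``x0`` is the start point on the natural (a..e) scale; the default starts
    from the energy-independent model k = 1.
    """
    kvs, hus, refs, wts, ids = _collect(series, TissueClass.BONE, reference_kv, weighted)
    if len(np.unique(kvs)) < 5:
        raise UnderdeterminedFitError(
            f"bone fit needs >= 5 distinct tube potentials, got {len(np.unique(kvs))}"
        )
    s = kvs / KV_SCALE
    # design matrix for k's coefficients on the kV/100 scale, times the anchor
    V = np.vander(s, 5)  # columns s^4 .. s^0
    A = V * (refs * wts)[:, None]
    y = hus * wts

    scale_up = np.array([KV_SCALE**4, KV_SCALE**3, KV_SCALE**2, KV_SCALE, 1.0])
    if x0 is None:
        p0 = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    else:
        p0 = np.asarray(x0, dtype=float) * scale_up

    if loss == "l2":
        sol = least_squares(
            lambda p: A @ p - y, p0, jac=lambda p: A, method="lm",
            ftol=FTOL, xtol=1e-14, gtol=1e-12,
        )
        p, converged, message = sol.x, sol.status > 0, sol.message
    elif loss == "l1":
        obj = lambda p: np.sum(np.abs(A @ p - y))
        start = np.linalg.lstsq(A, y, rcond=None)[0] if x0 is None else p0
        sol = minimize(obj, start, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-10, "maxiter": 20000})
        p, converged, message = sol.x, bool(sol.success), sol.message
    else:
        raise InvalidInputError(f"unknown loss {loss!r} (expected 'l2' or 'l1')")

    coeffs = p / scale_up
    model = BoneEnergyModel(*coeffs, reference_kv=float(reference_kv))
    res = hus - model.k(kvs) * refs
    sse = float(np.sum(res**2))
    return FitResult(
        model=model,
        sse=sse,
        rmse=float(np.sqrt(sse / len(res))),
        per_series_residuals=_split_residuals(ids, kvs, res),
        n_points=len(res),
        converged=converged,
        message=str(message),
    )


def fit_adipose_model(
    series: Sequence[HUMeasurementSeries],
    reference_kv: float = 120.0,
    *,
    weighted: bool = False,
) -> FitResult:
    """Fit the quadratic adipose offset delta(kV); linear, solved in closed form.

    Minimises ``sum (HU_s(ref) + delta(kV) - HU_s(kV))^2`` over (alpha, beta,
    gamma) by weighted linear least squares.
    """
    kvs, hus, refs, wts, ids = _collect(series, TissueClass.ADIPOSE, reference_kv, weighted)
    if len(np.unique(kvs)) < 3:
        raise UnderdeterminedFitError(
            f"adipose fit needs >= 3 distinct tube potentials, got {len(np.unique(kvs))}"
        )
    s = kvs / KV_SCALE
    A = np.vander(s, 3) * wts[:, None]
    y = (hus - refs) * wts
    p, *_ = np.linalg.lstsq(A, y, rcond=None)
    scale_up = np.array([KV_SCALE**2, KV_SCALE, 1.0])
    alpha, beta, gamma = p / scale_up
    model = AdiposeDeltaModel(alpha=alpha, beta=beta, gamma=gamma,
                              reference_kv=float(reference_kv))
    res = hus - (refs + model.delta(kvs))
    sse = float(np.sum(res**2))
    return FitResult(
        model=model,
        sse=sse,
        rmse=float(np.sqrt(sse / len(res))),
        per_series_residuals=_split_residuals(ids, kvs, res),
        n_points=len(res),
        converged=True,
        message="closed-form linear least squares",
    )


def goodness_of_fit(
    model: TissueModel,
    series: Sequence[HUMeasurementSeries],
    reference_kv: Optional[float] = None,
) -> FitResult:
    """Residual summary of an existing model against measurement series.

    Residuals are measured minus predicted, each series anchored at its
    reference-kV measurement (soft tissue: at the model constant).
    """
    if isinstance(model, BoneEnergyModel):
        tissue = TissueClass.BONE
    elif isinstance(model, AdiposeDeltaModel):
        tissue = TissueClass.ADIPOSE
    else:
        tissue = TissueClass.SOFT
    ref = model.reference_kv if reference_kv is None else reference_kv
    if not series:
        return FitResult(model=model, sse=0.0, rmse=float("nan"),
                         per_series_residuals={}, n_points=0, converged=True,
                         message="no data")
    if tissue is TissueClass.SOFT:
        kvs, hus, ids = [], [], []
        for srs in series:
            if srs.tissue_class is not tissue:
                raise ConfigurationError(
                    f"series {srs.sample_id!r} is {srs.tissue_class.value}, expected soft")
            for kv, hu, _sd, _n in srs.points:
                kvs.append(kv); hus.append(hu); ids.append(srs.sample_id)
        kvs, hus = np.array(kvs), np.array(hus)
        res = hus - model.hu_const
    else:
        kvs, hus, refs, _wts, ids = _collect(series, tissue, ref, weighted=False)
        pred = model.k(kvs) * refs if tissue is TissueClass.BONE else refs + model.delta(kvs)
        res = hus - pred
    sse = float(np.sum(res**2))
    return FitResult(
        model=model,
        sse=sse,
        rmse=float(np.sqrt(sse / len(res))),
        per_series_residuals=_split_residuals(ids, kvs, res),
        n_points=len(res),
        converged=True,
    )


# --- CSV interchange --------------------------------------------------------

SERIES_COLUMNS = ["sample_id", "tissue_class", "kv", "hu_mean", "hu_sd", "n_voxels"]


def read_series_csv(path: str | Path) -> list[HUMeasurementSeries]:
    """Read measurement series from a long-format CSV.

    Required columns: sample_id, tissue_class, kv, hu_mean; optional hu_sd,
    n_voxels.  Raises with the offending row index on malformed values.
    """
    df = pd.read_csv(path)
    missing = {"sample_id", "tissue_class", "kv", "hu_mean"} - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    for col in ("kv", "hu_mean"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad) or df[col].isna().any():
            row = int(bad[0]) if len(bad) else int(df.index[df[col].isna()][0])
            raise InvalidInputError(f"{path}: non-numeric or missing {col!r} at row {row}")
    out = []
    for (sid, tcls), grp in df.groupby(["sample_id", "tissue_class"], sort=False):
        sd = grp["hu_sd"] if "hu_sd" in grp else pd.Series([None] * len(grp))
        nv = grp["n_voxels"] if "n_voxels" in grp else pd.Series([None] * len(grp))
        pts = tuple(
            (kv, hu, None if pd.isna(s) else float(s), None if pd.isna(n) else int(n))
            for kv, hu, s, n in zip(grp["kv"], grp["hu_mean"], sd, nv)
        )
        out.append(HUMeasurementSeries(str(sid), TissueClass(tcls), pts))
    return out


def write_series_csv(series: Sequence[HUMeasurementSeries], path: str | Path) -> None:
    rows = [
        {"sample_id": s.sample_id, "tissue_class": s.tissue_class.value,
         "kv": kv, "hu_mean": hu, "hu_sd": sd, "n_voxels": n}
        for s in series for kv, hu, sd, n in s.points
    ]
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(path, index=False)


def write_residuals_csv(result: FitResult, path: str | Path) -> None:
    rows = [
        {"sample_id": sid, "kv": kv, "residual_hu": r}
        for sid, pairs in result.per_series_residuals.items()
        for kv, r in pairs
    ]
    pd.DataFrame(rows, columns=["sample_id", "kv", "residual_hu"]).to_csv(path, index=False)
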