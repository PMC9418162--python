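"""Tissue CT-number energy-dependence models for tube potentials of 70-140 kV.

CT numbers (Hounsfield units) of bone and adipose tissue depend on the tube
potential because their effective atomic numbers differ from water.  Given a
single measurement at a reference tube potential (120 kV by convention), the
models here predict the CT number at any other kV in the validated range:

* bone:     ``HU(kV) = k(kV) * HU(ref)`` with ``k`` a quartic polynomial in kV,
* adipose:  ``HU(kV) = HU(ref) + delta(kV)`` with ``delta`` a quadratic in kV,
* soft tissue (muscle, parenchyma): constant, i.e. no energy dependence.

The multiplicative form for bone captures the mineral-content scaling of
attenuation; the additive form for fat captures its roughly density-independent
spectral shift below water.  Coefficients derived from fresh bovine/porcine
tissue scans at 70/80/100/120/140 kV ship with the package
(:func:`reference_models`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Union

import numpy as np

from .exceptions import (
    ConfigurationError,
    EnergyRangeWarning,
    InvalidInputError,
    InvalidModelError,
)

__all__ = [
    "TissueClass",
    "BoneEnergyModel",
    "AdiposeDeltaModel",
    "SoftTissueModel",
    "TissueTarget",
    "evaluate_k",
    "evaluate_delta",
    "predict_bone_hu",
    "predict_adipose_hu",
    "predict_hu",
    "rebase_reference",
    "reference_models",
    "save_model",
    "load_model",
]

#: Validated tube-potential range of the reference coefficient set, in kV.
DEFAULT_VALID_RANGE: tuple[float, float] = (70.0, 140.0)
DEFAULT_REFERENCE_KV: float = 120.0

# kV is divided by this before polynomial evaluation; kV^4 ~ 4e8 at 140 kV
# would otherwise dominate the conditioning of fits and evaluations.
KV_SCALE: float = 100.0


class TissueClass(str, Enum):
    """Tissue categories distinguished by their CT-number energy dependence."""

    BONE = "bone"
    SOFT = "soft"
    ADIPOSE = "adipose"


def _check_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise InvalidInputError(f"{name} must be finite, got {v!r}")


def _check_kv(kv, valid_range: tuple[float, float]):
    arr = np.asarray(kv, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError(f"tube potential must be finite, got {kv!r}")
    lo, hi = valid_range
    if np.any(arr < lo) or np.any(arr > hi):
        warnings.warn(
            f"tube potential outside validated range [{lo:g}, {hi:g}] kV; "
            "extrapolating the fitted polynomial",
            EnergyRangeWarning,
            stacklevel=3,
        )
    return arr


@dataclass(frozen=True)
class BoneEnergyModel:
    """Quartic multiplicative energy model for bone tissue.

    ``k(kV) = a*kV^4 + b*kV^3 + c*kV^2 + d*kV + e`` converts a bone CT number
    measured at ``reference_kv`` to any tube potential:
    ``HU(kV) = k(kV) * HU(reference_kv)``.

    Coefficients are stored on the natural kV scale (units kV^-4 ... 1);
    evaluation internally rescales kV by 1/100 for conditioning.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    reference_kv: float = DEFAULT_REFERENCE_KV
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE

    def __post_init__(self) -> None:
        _check_finite("coefficient", self.a, self.b, self.c, self.d, self.e)
        _check_finite("reference_kv", self.reference_kv)
        lo, hi = self.valid_range
        if not lo < hi:
            raise InvalidInputError(f"valid_range must be increasing, got {self.valid_range}")

    @property
    def scaled_coefficients(self) -> np.ndarray:
        """Coefficients of k as a polynomial in kV/100, highest order first."""
        s = KV_SCALE
        return np.array([self.a * s**4, self.b * s**3, self.c * s**2, self.d * s, self.e])

    def k(self, kv):
        """Multiplicative factor k(kV); scalar in, scalar out."""
        arr = _check_kv(kv, self.valid_range)
        out = np.polyval(self.scaled_coefficients, arr / KV_SCALE)
        return float(out) if np.isscalar(kv) or out.ndim == 0 else out

    def predict(self, hu_ref: float, kv):
        """CT number at ``kv`` of bone measured as ``hu_ref`` at the reference kV."""
        return self.k(kv) * hu_ref


@dataclass(frozen=True)
class AdiposeDeltaModel:
    """Quadratic additive energy model for adipose tissue.

    ``delta(kV) = alpha*kV^2 + beta*kV + gamma`` is the offset to add to an
    adipose CT number measured at ``reference_kv``:
    ``HU(kV) = HU(reference_kv) + delta(kV)``.  The offset is negative below
    the reference potential (fat attenuates less at softer spectra) and by
    construction near zero at the reference.
    """

    alpha: float
    beta: float
    gamma: float
    reference_kv: float = DEFAULT_REFERENCE_KV
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE

    def __post_init__(self) -> None:
        _check_finite("coefficient", self.alpha, self.beta, self.gamma)
        _check_finite("reference_kv", self.reference_kv)
        lo, hi = self.valid_range
        if not lo < hi:
            raise InvalidInputError(f"valid_range must be increasing, got {self.valid_range}")

    @property
    def scaled_coefficients(self) -> np.ndarray:
        s = KV_SCALE
        return np.array([self.alpha * s**2, self.beta * s, self.gamma])

    def delta(self, kv):
        """Additive offset delta(kV) in HU."""
        arr = _check_kv(kv, self.valid_range)
        out = np.polyval(self.scaled_coefficients, arr / KV_SCALE)
        return float(out) if np.isscalar(kv) or out.ndim == 0 else out

    def predict(self, hu_ref: float, kv):
        return hu_ref + self.delta(kv)


@dataclass(frozen=True)
class SoftTissueModel:
    """Constant model for soft tissue: CT number independent of tube potential.

    Muscle and organ parenchyma are close to radiologic water equivalence, so
    a single CT number (default 65 HU, mid soft-tissue range) applies at all kV.
    """

    hu_const: float = 65.0
    reference_kv: float = DEFAULT_REFERENCE_KV
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE

    def __post_init__(self) -> None:
        _check_finite("hu_const", self.hu_const)

    def predict(self, hu_ref: float | None = None, kv=None):
        """CT number at any kV; ``hu_ref`` overrides the stored constant."""
        value = self.hu_const if hu_ref is None else hu_ref
        if kv is None or np.isscalar(kv):
            return float(value)
        return np.full(np.shape(kv), float(value))


TissueModel = Union[BoneEnergyModel, AdiposeDeltaModel, SoftTissueModel]


@dataclass(frozen=True)
class TissueTarget:
    """A tissue to be predicted or mimicked: class + CT number at the reference kV."""

    tissue_class: TissueClass
    hu_ref: float
    reference_kv: float = DEFAULT_REFERENCE_KV

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissue_class", TissueClass(self.tissue_class))
        _check_finite("hu_ref", self.hu_ref)
        if self.hu_ref <= -1000:
            raise InvalidInputError(f"hu_ref must exceed -1000 HU (air), got {self.hu_ref}")
        if self.tissue_class is TissueClass.BONE and self.hu_ref <= 0:
            raise InvalidInputError("bone targets must have positive hu_ref")
        if self.tissue_class is TissueClass.ADIPOSE and self.hu_ref >= 0:
            raise InvalidInputError("adipose targets must have negative hu_ref")


def evaluate_k(model: BoneEnergyModel, kv):
    """Evaluate the bone multiplicative factor k at tube potential ``kv``."""
    return model.k(kv)


def evaluate_delta(model: AdiposeDeltaModel, kv):
    """Evaluate the adipose additive offset delta at tube potential ``kv``."""
    return model.delta(kv)


def predict_bone_hu(model: BoneEnergyModel, target: TissueTarget, kv):
    """CT number of a bone target at ``kv``: k(kV) * HU(ref); linear in hu_ref."""
    if target.tissue_class is not TissueClass.BONE:
        raise ConfigurationError(f"expected a bone target, got {target.tissue_class.value}")
    if target.reference_kv != model.reference_kv:
        raise ConfigurationError(
            f"target anchored at {target.reference_kv} kV but model reference "
            f"is {model.reference_kv} kV; rebase the model first"
        )
    return model.predict(target.hu_ref, kv)


def predict_adipose_hu(model: AdiposeDeltaModel, target: TissueTarget, kv):
    """CT number of an adipose target at ``kv``: HU(ref) + delta(kV)."""
    if target.tissue_class is not TissueClass.ADIPOSE:
        raise ConfigurationError(f"expected an adipose target, got {target.tissue_class.value}")
    if target.reference_kv != model.reference_kv:
        raise ConfigurationError(
            f"target anchored at {target.reference_kv} kV but model reference "
            f"is {model.reference_kv} kV; rebase the model first"
        )
    return model.predict(target.hu_ref, kv)


def predict_hu(model: TissueModel, hu_ref: float, kv):
    """Dispatch prediction on the model type (bone multiplicative, adipose
    additive, soft constant) without constructing a :class:`TissueTarget`."""
    if isinstance(model, SoftTissueModel):
        return model.predict(hu_ref, kv)
    return model.predict(hu_ref, kv)


def rebase_reference(model: TissueModel, new_reference_kv: float):
    """Re-anchor a model at a different reference tube potential.

    Bone: divides all coefficients by k(new_ref) so k'(new_ref) = 1; a CT
    number measured at the new reference then predicts identically to chaining
    through the old reference.  Adipose: shifts gamma by -delta(new_ref) so
    delta'(new_ref) = 0.  Soft tissue is unaffected apart from the bookkeeping.
    """
    _check_finite("new_reference_kv", new_reference_kv)
    lo, hi = model.valid_range
    if not lo <= new_reference_kv <= hi:
        warnings.warn(
            f"rebasing outside validated range [{lo:g}, {hi:g}] kV",
            EnergyRangeWarning,
            stacklevel=2,
        )
    if isinstance(model, BoneEnergyModel):
        k_new = model.k(new_reference_kv)
        if k_new <= 0:
            raise InvalidModelError(
                f"k({new_reference_kv:g}) = {k_new:g} <= 0; cannot rebase"
            )
        return BoneEnergyModel(
            a=model.a / k_new,
            b=model.b / k_new,
            c=model.c / k_new,
            d=model.d / k_new,
            e=model.e / k_new,
            reference_kv=float(new_reference_kv),
            valid_range=model.valid_range,
        )
    if isinstance(model, AdiposeDeltaModel):
        shift = model.delta(new_reference_kv)
        return AdiposeDeltaModel(
            alpha=model.alpha,
            beta=model.beta,
            gamma=model.gamma - shift,
            reference_kv=float(new_reference_kv),
            valid_range=model.valid_range,
        )
    if isinstance(model, SoftTissueModel):
        return replace(model, reference_kv=float(new_reference_kv))
    raise InvalidInputError(f"cannot rebase object of type {type(model).__name__}")


def reference_models() -> tuple[BoneEnergyModel, AdiposeDeltaModel]:
    """The packaged coefficient sets fitted to fresh bovine/porcine tissue scans.

    The bone quartic and adipose quadratic were determined from multi-sample
    HU measurements at 70, 80, 100, 120 and 140 kV; coefficients are carried
    verbatim as fitted (k(120) = 0.9962, not renormalised to exactly 1 --
    use :func:`rebase_reference` if exact self-consistency at the anchor is
    required).
    """
    bone = BoneEnergyModel(
        a=1.54392e-08,
        b=-8.15985e-06,
        c=1.63309e-03,
        d=-1.50596e-01,
        e=6.45,
    )
    adipose = AdiposeDeltaModel(
        alpha=-6.80240e-03,
        beta=1.9698,
        gamma=-138.43,
    )
    return bone, adipose


# --- JSON serialization -----------------------------------------------------

_MODEL_TYPES = {
    "bone_energy": BoneEnergyModel,
    "adipose_delta": AdiposeDeltaModel,
    "soft_constant": SoftTissueModel,
}


def _model_type_name(model: TissueModel) -> str:
    for name, cls in _MODEL_TYPES.items():
        if type(model) is cls:
            return name
    raise InvalidInputError(f"unknown model type {type(model).__name__}")


def model_to_dict(model: TissueModel, provenance: str = "") -> dict:
    """Flat JSON-ready representation (round-trips bit-identically)."""
    if isinstance(model, BoneEnergyModel):
        coeffs = {"a": model.a, "b": model.b, "c": model.c, "d": model.d, "e": model.e}
    elif isinstance(model, AdiposeDeltaModel):
        coeffs = {"alpha": model.alpha, "beta": model.beta, "gamma": model.gamma}
    else:
        coeffs = {"hu_const": model.hu_const}
    return {
        "model_type": _model_type_name(model),
        "coefficients": coeffs,
        "reference_kv": model.reference_kv,
        "valid_range": list(model.valid_range),
        "provenance": provenance,
    }


def model_from_dict(doc: dict) -> TissueModel:
    try:
        cls = _MODEL_TYPES[doc["model_type"]]
    except KeyError as exc:
        raise InvalidInputError(f"unknown model_type {doc.get('model_type')!r}") from exc
    return cls(
        **doc["coefficients"],
        reference_kv=float(doc["reference_kv"]),
        valid_range=tuple(doc["valid_range"]),
    )


def save_model(model: TissueModel, path: str | Path, provenance: str = "") -> None:
    Path(path).write_text(json.dumps(model_to_dict(model, provenance), indent=2) + "\n")


def load_model(path: str | Path) -> TissueModel:
    return model_from_dict(json.loads(Path(path).read_text()))
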