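"""Packaged reference data: tissue model coefficients, the printing-material
library, and the published density-reduction plans.

The material library carries each material's 120-kV CT number and its per-kV
offset to the equal-CT-number tissue model (0 at 120 kV by construction),
together with polymer/product metadata.  The fill-plan reference holds the
published filling ratios and residual delta-HU values for the four canonical
tissue targets (soft bone 350 HU, average whole bone 500 HU, dense/cortical
bone 1000 HU, average adipose tissue -80 HU); it serves as the expected-value
fixture for regression tests, never as an input to computation.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import InvalidInputError
from .matching import MaterialRecord, read_material_library_csv
from .models import AdiposeDeltaModel, BoneEnergyModel, reference_models

__all__ = [
    "data_path",
    "load_material_library",
    "material_by_name",
    "load_fill_plan_reference",
    "reference_tables",
    "data_file_sha256",
    "reference_models",
]

_DATA_FILES = ("material_library.csv", "fill_plan_reference.csv")


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    if name not in _DATA_FILES:
        raise InvalidInputError(f"unknown data file {name!r}; have {_DATA_FILES}")
    return Path(str(resources.files("ctphantom") / "data" / name))


def load_material_library(path: str | Path | None = None) -> list[MaterialRecord]:
    """Material records from the packaged (or a user-supplied) library CSV.

    Materials without a characterised 120-kV CT number are metadata-only and
    omitted from the returned records.
    """
    return read_material_library_csv(path or data_path("material_library.csv"))


def material_by_name(name: str, path: str | Path | None = None) -> MaterialRecord:
    for mat in load_material_library(path):
        if mat.name == name:
            return mat
    raise InvalidInputError(f"material {name!r} not in library")


def load_fill_plan_reference() -> pd.DataFrame:
    """Published filling ratios and per-kV delta-HU for the canonical targets."""
    return pd.read_csv(data_path("fill_plan_reference.csv"))


def load_material_metadata() -> pd.DataFrame:
    """Full library table including metadata-only (uncharacterised) materials."""
    return pd.read_csv(data_path("material_library.csv"))


def reference_tables() -> dict:
    """All packaged reference data in one bundle."""
    bone, adipose = reference_models()
    return {
        "bone_model": bone,
        "adipose_model": adipose,
        "materials": load_material_library(),
        "material_metadata": load_material_metadata(),
        "fill_plan_reference": load_fill_plan_reference(),
    }


def data_file_sha256(name: str) -> str:
    """SHA-256 of a packaged data file (guards fixtures against silent edits)."""
    return hashlib.sha256(data_path(name).read_bytes()).hexdigest()
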