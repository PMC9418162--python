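"""Synthetic HU measurement series and multi-kV phantom volumes.

Real multi-energy scans of tissue specimens are not redistributable, so the
generators here produce data with the statistical structure the analysis
assumes: per-sample HU-vs-kV series follow the packaged tissue energy models
plus independent Gaussian noise, and voxel phantoms contain geometric regions
(graded-density bone, cortical shell, marrow, muscle, fat) whose per-kV
voxel values follow the same models.  An optional Gaussian blur emulates
partial-volume mixing at region boundaries.  Everything is reproducible from
an integer seed.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .exceptions import InvalidInputError
from .fitting import HUMeasurementSeries
from .models import (
    AdiposeDeltaModel,
    BoneEnergyModel,
    SoftTissueModel,
    TissueClass,
    reference_models,
)
from .segmentation import CtVolumeSet

__all__ = [
    "SeriesSpec",
    "PhantomSpec",
    "Region",
    "Box",
    "Sphere",
    "Cylinder",
    "Shell",
    "make_measurement_series",
    "make_phantom_volume_set",
    "default_bone_phantom",
    "load_series_spec",
    "load_phantom_spec",
]

logger = logging.getLogger(__name__)

DEFAULT_KV_GRID: tuple[float, ...] = (70.0, 80.0, 100.0, 120.0, 140.0)

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


# --- geometry primitives (voxel coordinates) --------------------------------

@dataclass(frozen=True)
class Box:
    """Axis-aligned box with half-open voxel index bounds [lo, hi)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def mask(self, shape: tuple[int, ...]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        sl = tuple(slice(max(l, 0), min(h, n)) for l, h, n in zip(self.lo, self.hi, shape))
        m[sl] = True
        return m


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def mask(self, shape: tuple[int, ...]) -> np.ndarray:
        grids = np.indices(shape, dtype=float)
        r2 = sum((g - c) ** 2 for g, c in zip(grids, self.center))
        return r2 <= self.radius**2


@dataclass(frozen=True)
class Cylinder:
    """Axis-aligned cylinder; ``axis`` is the long axis (0, 1 or 2)."""

    center: tuple[float, float, float]
    radius: float
    half_length: float
    axis: int = 2

    def mask(self, shape: tuple[int, ...]) -> np.ndarray:
        grids = np.indices(shape, dtype=float)
        radial = [i for i in range(3) if i != self.axis]
        r2 = sum((grids[i] - self.center[i]) ** 2 for i in radial)
        along = np.abs(grids[self.axis] - self.center[self.axis])
        return (r2 <= self.radius**2) & (along <= self.half_length)


@dataclass(frozen=True)
class Shell:
    """Outer primitive minus inner primitive (e.g. a cortical shell)."""

    outer: Union[Box, Sphere, Cylinder]
    inner: Union[Box, Sphere, Cylinder]

    def mask(self, shape: tuple[int, ...]) -> np.ndarray:
        return self.outer.mask(shape) & ~self.inner.mask(shape)


Geometry = Union[Box, Sphere, Cylinder, Shell]


@dataclass(frozen=True)
class Region:
    """A labelled homogeneous tissue region of a phantom."""

    label: str
    geometry: Geometry
    tissue_class: TissueClass
    hu_ref: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissue_class", TissueClass(self.tissue_class))


# --- specs ------------------------------------------------------------------

@dataclass(frozen=True)
class SeriesSpec:
    """Recipe for simulated HU-vs-kV measurement series of one tissue class.

    Reference CT numbers are drawn uniformly from ``hu_ref_range``; values at
    each tube potential follow the packaged tissue models plus independent
    Gaussian noise of ``noise_sd`` HU (applied at every grid point including
    the reference, as in a real measurement).
    """

    tissue_class: TissueClass
    n_series: int
    hu_ref_range: tuple[float, float]
    kv_grid: tuple[float, ...] = DEFAULT_KV_GRID
    noise_sd: float = 0.0
    reference_kv: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissue_class", TissueClass(self.tissue_class))
        lo, hi = self.hu_ref_range
        if lo > hi:
            raise InvalidInputError(f"hu_ref_range must be increasing, got {self.hu_ref_range}")
        if self.tissue_class is TissueClass.BONE and lo <= 0:
            raise InvalidInputError("bone hu_ref_range must be positive")
        if self.tissue_class is TissueClass.ADIPOSE and hi >= 0:
            raise InvalidInputError("adipose hu_ref_range must be negative")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.n_series < 0:
            raise InvalidInputError("n_series must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a co-registered multi-kV voxel phantom.

    Background is water (0 HU, energy-independent); regions are painted in
    order, later regions overwriting earlier ones where they overlap.  The
    default 64-voxel cube keeps the full segmentation pipeline at sub-second
    runtimes.
    """

    regions: tuple[Region, ...]
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    kv_grid: tuple[float, ...] = DEFAULT_KV_GRID
    noise_sd: float = 0.0
    blur_fwhm: Optional[float] = None
    reference_kv: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise InvalidInputError(f"region labels must be unique, got {labels}")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if float(self.reference_kv) not in [float(k) for k in self.kv_grid]:
            raise InvalidInputError(
                f"kv_grid must include the reference kV {self.reference_kv:g}")


def _models_or_default(models):
    if models is None:
        bone, adipose = reference_models()
        return bone, adipose, SoftTissueModel()
    return models


def _predict(tissue_class: TissueClass, hu_ref: float, kv: float,
             bone: BoneEnergyModel, adipose: AdiposeDeltaModel,
             soft: SoftTissueModel) -> float:
    if tissue_class is TissueClass.BONE:
        return bone.predict(hu_ref, kv)
    if tissue_class is TissueClass.ADIPOSE:
        return adipose.predict(hu_ref, kv)
    return soft.predict(hu_ref, kv)


def make_measurement_series(
    spec: SeriesSpec,
    models: Optional[tuple[BoneEnergyModel, AdiposeDeltaModel, SoftTissueModel]] = None,
) -> list[HUMeasurementSeries]:
    """Simulate per-sample HU-vs-kV series according to ``spec``.

    The reference tube potential is always included in the grid, so every
    series can anchor a fit.  Bit-identical for identical specs.
    """
    bone, adipose, soft = _models_or_default(models)
    rng = np.random.default_rng(spec.seed)
    grid = sorted({float(k) for k in spec.kv_grid} | {float(spec.reference_kv)})
    out = []
    for i in range(spec.n_series):
        hu_ref = rng.uniform(*spec.hu_ref_range)
        noise = rng.normal(0.0, spec.noise_sd, size=len(grid)) if spec.noise_sd > 0 \
            else np.zeros(len(grid))
        pts = tuple(
            (kv, _predict(spec.tissue_class, hu_ref, kv, bone, adipose, soft) + eps,
             spec.noise_sd if spec.noise_sd > 0 else None, None)
            for kv, eps in zip(grid, noise)
        )
        out.append(HUMeasurementSeries(
            sample_id=f"{spec.tissue_class.value}-{i:03d}",
            tissue_class=spec.tissue_class,
            points=pts,
        ))
    return out


def make_phantom_volume_set(
    spec: PhantomSpec,
    models: Optional[tuple[BoneEnergyModel, AdiposeDeltaModel, SoftTissueModel]] = None,
) -> tuple[CtVolumeSet, np.ndarray]:
    """Build aligned per-kV volumes and the ground-truth label map.

    Per kV: regions are painted over a water background at their model-
    predicted CT number, then an optional Gaussian blur (``blur_fwhm`` mm,
    partial-volume emulation) and voxelwise Gaussian noise are applied.  The
    label map (0 = background, i+1 = region i) is unblurred ground truth.
    """
    bone, adipose, soft = _models_or_default(models)
    shape = tuple(int(n) for n in spec.grid_shape)
    masks = []
    label_map = np.zeros(shape, dtype=np.int16)
    for i, region in enumerate(spec.regions):
        m = region.geometry.mask(shape)
        overlap = m & (label_map > 0)
        if overlap.any():
            logger.info("region %r overwrites %d voxels of earlier regions",
                        region.label, int(overlap.sum()))
        label_map[m] = i + 1
        masks.append(m)
    # paint from the final label map so overlaps resolve identically in HU and labels
    volumes = {}
    rng = np.random.default_rng(spec.seed)
    sigma_vox = None
    if spec.blur_fwhm:
        sigma_vox = [spec.blur_fwhm * _FWHM_TO_SIGMA / s for s in spec.voxel_spacing]
    for kv in sorted({float(k) for k in spec.kv_grid}):
        vol = np.zeros(shape, dtype=float)  # water background
        for i, region in enumerate(spec.regions):
            value = _predict(region.tissue_class, region.hu_ref, kv, bone, adipose, soft)
            vol[label_map == i + 1] = value
        if sigma_vox is not None:
            vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)
        volumes[kv] = vol
    return (
        CtVolumeSet(volumes=volumes, voxel_spacing=spec.voxel_spacing,
                    reference_kv=spec.reference_kv),
        label_map,
    )


def default_bone_phantom(noise_sd: float = 0.0, blur_fwhm: Optional[float] = None,
                         seed: int = 0, grid: int = 64) -> PhantomSpec:
    """A compact specimen-like phantom: graded-density bone cylinders with a
    cortical shell and marrow core, plus muscle and fat blocks, in water.

    Bone anchors are chosen so the 120 kV voxel values land on 200-HU
    density-bin centres (50 + i*200 HU), far from every bin edge and from
    the 300 HU bone threshold; each region then maps to exactly one density
    bin and, under noise, per-bin voxel selection stays effectively unbiased.
    """
    g = grid
    q = g // 4
    # center-of-bin reference CT numbers: value * k(120 kV) = 450, 850, 1250, 1650
    soft_b, whole_b, dense_b, cortical_b = 451.70, 853.22, 1254.73, 1656.25
    regions = (
        Region("muscle", Box((0, 0, 0), (g, q, g)), TissueClass.SOFT, 60.0),
        Region("fat", Box((0, q, 0), (g, 2 * q, g)), TissueClass.ADIPOSE, -80.0),
        Region("soft bone", Cylinder((q, 3 * q, g / 2), q * 0.45, g * 0.4, axis=2),
               TissueClass.BONE, soft_b),
        Region("whole bone", Cylinder((2 * q, 3 * q, g / 2), q * 0.45, g * 0.4, axis=2),
               TissueClass.BONE, whole_b),
        Region("dense bone", Cylinder((3 * q, 3 * q, g / 2), q * 0.45, g * 0.4, axis=2),
               TissueClass.BONE, dense_b),
        Region("cortical shell",
               Shell(Cylinder((2 * q, 3 * q, g / 2), q * 0.45, g * 0.4, axis=2),
                     Cylinder((2 * q, 3 * q, g / 2), q * 0.28, g * 0.4, axis=2)),
               TissueClass.BONE, cortical_b),
    )
    return PhantomSpec(regions=regions, grid_shape=(g, g, g), noise_sd=noise_sd,
                       blur_fwhm=blur_fwhm, seed=seed)


# --- TOML configuration -----------------------------------------------------

def _strict_keys(table: dict, allowed: set[str], where: str) -> None:
    unknown = set(table) - allowed
    if unknown:
        raise InvalidInputError(f"{where}: unknown keys {sorted(unknown)}")


_GEOMETRIES = {"box": Box, "sphere": Sphere, "cylinder": Cylinder}


def _geometry_from_dict(d: dict, where: str) -> Geometry:
    d = dict(d)
    kind = d.pop("kind", None)
    if kind == "shell":
        _strict_keys(d, {"outer", "inner"}, where)
        return Shell(_geometry_from_dict(d["outer"], where + ".outer"),
                     _geometry_from_dict(d["inner"], where + ".inner"))
    if kind not in _GEOMETRIES:
        raise InvalidInputError(f"{where}: unknown geometry kind {kind!r}")
    cls = _GEOMETRIES[kind]
    try:
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
    except TypeError as exc:
        raise InvalidInputError(f"{where}: {exc}") from exc


def load_series_spec(path: str | Path) -> SeriesSpec:
    """Read a [series] spec from TOML; unknown keys are rejected."""
    doc = tomllib.loads(Path(path).read_text())
    table = doc.get("series", doc)
    allowed = {"tissue_class", "n_series", "hu_ref_range", "kv_grid",
               "noise_sd", "reference_kv", "seed"}
    _strict_keys(table, allowed, "series")
    kwargs = dict(table)
    if "hu_ref_range" in kwargs:
        kwargs["hu_ref_range"] = tuple(kwargs["hu_ref_range"])
    if "kv_grid" in kwargs:
        kwargs["kv_grid"] = tuple(kwargs["kv_grid"])
    return SeriesSpec(**kwargs)


def load_phantom_spec(path: str | Path) -> PhantomSpec:
    """Read a [phantom] spec plus [[phantom.region]] tables from TOML."""
    doc = tomllib.loads(Path(path).read_text())
    table = dict(doc.get("phantom", doc))
    regions_raw = table.pop("region", [])
    allowed = {"grid_shape", "voxel_spacing", "kv_grid", "noise_sd",
               "blur_fwhm", "reference_kv", "seed"}
    _strict_keys(table, allowed, "phantom")
    regions = []
    for i, r in enumerate(regions_raw):
        where = f"phantom.region[{i}]"
        _strict_keys(r, {"label", "tissue_class", "hu_ref", "geometry"}, where)
        regions.append(Region(
            label=r["label"],
            geometry=_geometry_from_dict(r["geometry"], where + ".geometry"),
            tissue_class=TissueClass(r["tissue_class"]),
            hu_ref=float(r["hu_ref"]),
        ))
    kwargs = dict(table)
    for key in ("grid_shape", "voxel_spacing", "kv_grid"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return PhantomSpec(regions=tuple(regions), **kwargs)
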