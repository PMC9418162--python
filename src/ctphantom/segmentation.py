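"""Threshold segmentation and per-segment HU statistics on multi-kV CT volumes.

The extraction procedure works on the reference-kV (120 kV) volume: bone is
segmented at a 300 HU surface threshold, the cortical compartment at 900 HU,
yellow marrow by the midpoint of the cortical and marrow means, and adipose
tissue with an upper threshold of -20 HU (plus a configurable lower bound to
exclude air).  Bone voxels are then stratified into 200-HU-wide density bins
starting at -50 HU (centres 50, 250, ... HU, open-ended top bin).  All labels
defined on the reference volume are transferred unchanged to the co-registered
volumes at other tube potentials, so each segment's statistics are computed
over exactly the same voxel set at every kV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import AlignmentError, InvalidInputError

__all__ = [
    "CtVolumeSet",
    "DensityBinning",
    "SegmentStats",
    "segment_bone_mask",
    "segment_cortical",
    "marrow_threshold",
    "segment_adipose",
    "bin_bone_density",
    "transfer_and_summarize",
    "stats_to_dataframe",
    "write_stats_csv",
    "load_volume_set",
    "save_volume_set",
    "save_label_map",
]

BONE_SURFACE_THRESHOLD = 300.0
CORTICAL_THRESHOLD = 900.0
ADIPOSE_UPPER = -20.0
ADIPOSE_LOWER = -200.0


@dataclass
class CtVolumeSet:
    """Co-registered CT volumes of one sample at several tube potentials.

    All volumes share shape and voxel spacing; registration happens upstream,
    so voxel (i, j, k) refers to the same anatomy in every volume.
    """

    volumes: dict[float, np.ndarray]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    reference_kv: float = 120.0

    def __post_init__(self) -> None:
        self.volumes = {float(k): np.asarray(v, dtype=float) for k, v in self.volumes.items()}
        if float(self.reference_kv) not in self.volumes:
            raise InvalidInputError(
                f"reference volume at {self.reference_kv:g} kV missing "
                f"(have {sorted(self.volumes)})")
        shapes = {v.shape for v in self.volumes.values()}
        if len(shapes) != 1:
            raise AlignmentError(f"volumes have differing shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[float(self.reference_kv)].shape

    @property
    def kv_grid(self) -> list[float]:
        return sorted(self.volumes)

    @property
    def reference_volume(self) -> np.ndarray:
        return self.volumes[float(self.reference_kv)]


@dataclass(frozen=True)
class DensityBinning:
    """Stratification of bone voxels by reference-kV CT number.

    Half-open bins ``[edge, edge + bin_width)`` start at ``first_lower_edge``;
    centres are ``first_lower_edge + bin_width/2 + i*bin_width``.  With the
    defaults (200 HU from -50 HU) the centres are 50, 250, ..., 1850 HU, and
    ``open_top`` adds an open-ended final bin (">1950") for extremely dense
    bone.  ``n_bins`` counts all bins including the open one.
    """

    bin_width: float = 200.0
    first_lower_edge: float = -50.0
    open_top: bool = True
    n_bins: int = 11

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.n_bins < 1:
            raise InvalidInputError("bin_width must be > 0 and n_bins >= 1")

    def bin_index(self, values: np.ndarray) -> np.ndarray:
        """0-based bin index per value; -1 marks values below the first edge.

        Values at or beyond the last closed edge go to the open top bin when
        ``open_top``; otherwise they also map to -1 (out of range).
        """
        v = np.asarray(values, dtype=float)
        idx = np.floor((v - self.first_lower_edge) / self.bin_width).astype(int)
        below = idx < 0
        if self.open_top:
            idx = np.minimum(idx, self.n_bins - 1)
        else:
            idx = np.where(idx >= self.n_bins, -1, idx)
        return np.where(below, -1, idx)

    def bin_center(self, i: int) -> float:
        return self.first_lower_edge + self.bin_width / 2 + i * self.bin_width

    def bin_label(self, i: int) -> str:
        if self.open_top and i == self.n_bins - 1:
            edge = self.first_lower_edge + i * self.bin_width
            return f">{edge:g} HU"
        return f"{self.bin_center(i):g} HU"


@dataclass
class SegmentStats:
    """Per-kV statistics of one segment over a fixed voxel set.

    ``per_kv`` maps tube potential to (mean HU, population SD HU, voxel
    count); the count is identical at every kV since the same labelled
    voxels are summarised in each co-registered volume.
    """

    segment_label: str
    per_kv: dict[float, tuple[float, float, int]]

    @property
    def n_voxels(self) -> int:
        return next(iter(self.per_kv.values()))[2] if self.per_kv else 0


def _threshold_mask(volume: np.ndarray, threshold: float, what: str,
                    largest_component: bool) -> np.ndarray:
    vol = np.asarray(volume, dtype=float)
    mask = vol >= threshold
    if not mask.any():
        warnings.warn(f"{what} mask is empty at threshold {threshold:g} HU",
                      UserWarning, stacklevel=3)
        return mask
    if largest_component:
        labels, n = ndimage.label(mask)
        if n > 1:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            mask = labels == (1 + int(np.argmax(sizes)))
    return mask


def segment_bone_mask(volume_ref: np.ndarray, threshold: float = BONE_SURFACE_THRESHOLD,
                      largest_component: bool = False) -> np.ndarray:
    """Bone mask on the reference volume: voxels >= 300 HU by default.

    ``largest_component`` keeps only the largest connected component, a crude
    stand-in for the manual contour cleanup used on complicated joints.
    """
    return _threshold_mask(volume_ref, threshold, "bone", largest_component)


def segment_cortical(volume_ref: np.ndarray, threshold: float = CORTICAL_THRESHOLD,
                     largest_component: bool = False) -> np.ndarray:
    """Cortical-bone mask: voxels >= 900 HU by default (a subset of the bone mask)."""
    return _threshold_mask(volume_ref, threshold, "cortical", largest_component)


def marrow_threshold(mean_cortical: float, mean_marrow: float) -> float:
    """50 % threshold between cortical bone and marrow: the midpoint of the means."""
    if not (np.isfinite(mean_cortical) and np.isfinite(mean_marrow)):
        raise InvalidInputError("means must be finite")
    if mean_cortical <= mean_marrow:
        raise InvalidInputError(
            f"cortical mean ({mean_cortical:g}) must exceed marrow mean ({mean_marrow:g})")
    return (mean_cortical + mean_marrow) / 2.0


def segment_adipose(volume_ref: np.ndarray, upper: float = ADIPOSE_UPPER,
                    lower: float = ADIPOSE_LOWER) -> np.ndarray:
    """Adipose mask: ``lower <= HU <= upper`` (default [-200, -20] HU).

    The upper bound separates fat from muscle; the lower bound excludes air
    and gas.  The [-140, -30] window sometimes used for human adipose
    segmentation is available by passing those bounds.
    """
    if lower >= upper:
        raise InvalidInputError(f"lower ({lower:g}) must be below upper ({upper:g})")
    vol = np.asarray(volume_ref, dtype=float)
    return (vol >= lower) & (vol <= upper)


def bin_bone_density(volume_ref: np.ndarray, bone_mask: np.ndarray,
                     binning: DensityBinning = DensityBinning()) -> np.ndarray:
    """Label map of density bins inside the bone mask.

    Returns an int array: 0 outside the mask, bin index + 1 inside.  Every
    masked voxel receives exactly one bin (a masked voxel below the first
    edge — impossible with the default 300 HU bone threshold — would raise).
    """
    vol = np.asarray(volume_ref, dtype=float)
    mask = np.asarray(bone_mask, dtype=bool)
    if vol.shape != mask.shape:
        raise AlignmentError(f"volume {vol.shape} vs mask {mask.shape}")
    if not mask.any():
        raise InvalidInputError("bone mask is empty; nothing to bin")
    idx = binning.bin_index(vol)
    if np.any((idx < 0) & mask):
        raise InvalidInputError(
            "masked voxels fall outside the binning range; lower first_lower_edge "
            "or enable open_top")
    labels = np.zeros(vol.shape, dtype=np.int16)
    labels[mask] = idx[mask] + 1
    return labels


def transfer_and_summarize(
    label_map: np.ndarray,
    volume_set: CtVolumeSet,
    binning: Optional[DensityBinning] = None,
    include_empty: bool = False,
) -> list[SegmentStats]:
    """Per-segment, per-kV mean/SD/count over the *same* voxel set at every kV.

    The label map (defined on the reference volume) is applied unchanged to
    each co-registered volume, guaranteeing equivalent ROI placement; SDs are
    population SDs.  Labels are named by bin when ``binning`` is given,
    otherwise "segment <label>".  Empty labels yield count 0 and NaN mean
    when ``include_empty``.
    """
    labels = np.asarray(label_map)
    if labels.shape != volume_set.shape:
        raise AlignmentError(
            f"label map shape {labels.shape} does not match volumes {volume_set.shape}")
    max_label = int(labels.max(initial=0))
    out: list[SegmentStats] = []
    for lab in range(1, max_label + 1):
        mask = labels == lab
        count = int(mask.sum())
        if count == 0 and not include_empty:
            continue
        name = binning.bin_label(lab - 1) if binning is not None else f"segment {lab}"
        per_kv: dict[float, tuple[float, float, int]] = {}
        for kv in volume_set.kv_grid:
            if count == 0:
                per_kv[kv] = (float("nan"), float("nan"), 0)
            else:
                vox = volume_set.volumes[kv][mask]
                per_kv[kv] = (float(vox.mean()), float(vox.std()), count)
        out.append(SegmentStats(segment_label=name, per_kv=per_kv))
    return out


def stats_to_dataframe(stats: Sequence[SegmentStats]) -> pd.DataFrame:
    rows = [
        {"segment_label": s.segment_label, "kv": kv,
         "mean_hu": mean, "sd_hu": sd, "n_voxels": n}
        for s in stats for kv, (mean, sd, n) in sorted(s.per_kv.items())
    ]
    return pd.DataFrame(rows, columns=["segment_label", "kv", "mean_hu", "sd_hu", "n_voxels"])


def write_stats_csv(stats: Sequence[SegmentStats], path: str | Path) -> None:
    stats_to_dataframe(stats).to_csv(path, index=False)


# --- NIfTI I/O --------------------------------------------------------------

def load_volume_set(paths: dict[float, str | Path], reference_kv: float = 120.0,
                    ) -> CtVolumeSet:
    """Load co-registered volumes from per-kV NIfTI files (HU voxel values)."""
    import nibabel as nib

    volumes = {}
    spacing = None
    for kv, path in paths.items():
        img = nib.load(str(path))
        volumes[float(kv)] = np.asarray(img.get_fdata(), dtype=float)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        if spacing is not None and zooms != spacing:
            raise AlignmentError(f"{path}: voxel spacing {zooms} differs from {spacing}")
        spacing = zooms
    return CtVolumeSet(volumes=volumes, voxel_spacing=spacing or (1.0, 1.0, 1.0),
                       reference_kv=reference_kv)


def save_volume_set(volume_set: CtVolumeSet, directory: str | Path,
                    prefix: str = "volume") -> dict[float, Path]:
    """Write one NIfTI per kV; returns the path map."""
    import nibabel as nib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag([*volume_set.voxel_spacing, 1.0])
    out = {}
    for kv, vol in volume_set.volumes.items():
        path = directory / f"{prefix}_{kv:g}kV.nii.gz"
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
        out[kv] = path
    return out


def save_label_map(label_map: np.ndarray, path: str | Path,
                   voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> None:
    import nibabel as nib

    affine = np.diag([*voxel_spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(label_map, dtype=np.int16), affine), str(path))
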