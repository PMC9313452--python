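"""Volume I/O, VOI cropping, slice extraction and intensity normalization.

Conventions (fixed and tested):

* voxel indices are 0-based; crop windows are half-open,
* a VOI center voxel ``c`` maps to the window ``[c - edge//2, c - edge//2 + edge)``
  per axis (for even edges the "center" is the lower-middle voxel),
* slice IDs are 1-based: slice ID ``k`` is plane ``k-1`` along the slicing
  axis (default axis 0, configurable — the anatomical direction of the 20
  planes is an input, not something this stage decides),
* every slice is z-scored independently (mean 0, SD 1) before it reaches the
  contrastive or classification stages; a constant slice maps to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "VOISpec",
    "SliceInstance",
    "load_volume",
    "crop_voi",
    "extract_slices",
    "normalize_slice",
    "load_manifest",
    "cohort_to_slices",
]


@dataclass(frozen=True)
class VOISpec:
    """Cubic crop window: integer center voxel and edge length."""

    center: tuple[int, int, int]
    edge: int = 20


@dataclass
class SliceInstance:
    """One 2D plane of a subject's VOI: the unit of contrastive learning
    and of slice-level classification."""

    subject_id: str
    slice_id: int        # 1-based
    pixels: np.ndarray   # (edge, edge) float
    label: int           # inherited from the subject

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("slice pixels must be finite")


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (intensity array, 4x4 affine).

    Raises ValueError for non-3D images (a 2D image cannot hold a VOI).
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got {data.ndim}D data in {path}")
    return data, np.asarray(img.affine)


def crop_voi(volume: np.ndarray, spec: VOISpec) -> np.ndarray:
    """Crop the half-open window [c - edge//2, c - edge//2 + edge) per axis.

    Windows that touch outside the volume raise; there is no silent padding.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("crop_voi expects a 3D volume")
    starts = [int(c) - spec.edge // 2 for c in spec.center]
    for ax, start in enumerate(starts):
        if start < 0 or start + spec.edge > volume.shape[ax]:
            raise ValueError(
                f"VOI window [{start}, {start + spec.edge}) exceeds axis {ax} "
                f"extent {volume.shape[ax]}"
            )
    sl = tuple(slice(s, s + spec.edge) for s in starts)
    return volume[sl].copy()


def extract_slices(voi: np.ndarray, subject_id: str, label: int, axis: int = 0) -> list[SliceInstance]:
    """Split an edge^3 VOI into `edge` 2D instances along `axis`, slice IDs 1..edge."""
    voi = np.asarray(voi)
    if voi.ndim != 3 or len(set(voi.shape)) != 1:
        raise ValueError("VOI must be a cube")
    if axis not in (0, 1, 2):
        raise ValueError("axis must be 0, 1 or 2")
    moved = np.moveaxis(voi, axis, 0)
    return [
        SliceInstance(subject_id=subject_id, slice_id=k + 1, pixels=moved[k].copy(), label=label)
        for k in range(moved.shape[0])
    ]


def normalize_slice(pixels: np.ndarray) -> np.ndarray:
    """Per-slice standardization to mean 0 / SD 1; constant slices map to zeros.

    Invariant under positive affine rescaling of the input (a*x + b, a > 0),
    which is what makes differently-scaled scanner intensities commensurable.
    """
    pixels = np.asarray(pixels, dtype=float)
    sd = pixels.std()
    if sd == 0.0:
        return np.zeros_like(pixels)
    return (pixels - pixels.mean()) / sd


def load_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest CSV (subject_id, label, path, cx, cy, cz)."""
    manifest = pd.read_csv(path)
    required = {"subject_id", "label", "path", "cx", "cy", "cz"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    return manifest


def cohort_to_slices(cohort, axis: int = 0, normalize: bool = True) -> list[SliceInstance]:
    """Slice every subject of an in-memory cohort, optionally z-scoring each slice."""
    slices: list[SliceInstance] = []
    for rec in cohort:
        for inst in extract_slices(rec.volume, rec.subject_id, rec.label, axis=axis):
            if normalize:
                inst.pixels = normalize_slice(inst.pixels)
            slices.append(inst)
    return slices


def manifest_to_slices(manifest: pd.DataFrame, edge: int = 20, axis: int = 0,
                       normalize: bool = True) -> list[SliceInstance]:
    """Load each subject's volume, crop its VOI at the manifest center, slice it."""
    slices: list[SliceInstance] = []
    for row in manifest.itertuples(index=False):
        volume, _ = load_volume(Path(row.path))
        voi = crop_voi(volume, VOISpec(center=(int(row.cx), int(row.cy), int(row.cz)), edge=edge))
        for inst in extract_slices(voi, str(row.subject_id), int(row.label), axis=axis):
            if normalize:
                inst.pixels = normalize_slice(inst.pixels)
            slices.append(inst)
    return slices
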