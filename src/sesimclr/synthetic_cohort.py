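"""Synthetic cohort generator.

Emulates the shape of the study data — a cohort of adolescent students, each
contributing one 20x20x20-voxel volume of interest (VOI) cropped from the left
middle frontal gyrus, with a binary group label (0 = math, 1 = non-math; the
study cohort is 72 math + 51 non-math).  Downstream stages treat each VOI as a
bag of 20 two-dimensional slice instances.

The generative model is deliberately minimal: each volume is a smooth random
background field plus white noise; non-math (class 1) subjects additionally
carry a smooth Gaussian blob in a fixed sub-region of every slice, scaled per
slice index by an *effect profile*.  The default profile makes slice IDs 13-19
strongly informative and IDs 1, 2, 9, 20 essentially uninformative, mirroring
the per-slice difficulty pattern the classification stage is expected to
surface.  Nothing here claims to model MR physics; the generator exists so the
full pipeline is exercisable and testable without any imaging data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "CohortConfig",
    "SubjectRecord",
    "default_effect_profile",
    "generate_cohort",
    "slice_count",
    "write_cohort",
]


def default_effect_profile(n_slices: int = 20) -> np.ndarray:
    """Per-slice-ID effect sizes (arbitrary units, index 0 = slice ID 1).

    High effect (3.0) at slice IDs 13-19, near-zero at IDs 1, 2, 9 and 20,
    intermediate (1.5) elsewhere.  Only defined for the standard 20 slices;
    other lengths get a flat intermediate profile.
    """
    if n_slices != 20:
        return np.full(n_slices, 1.5)
    profile = np.full(20, 1.5)
    profile[[0, 1, 8, 19]] = 0.0   # slice IDs 1, 2, 9, 20
    profile[12:19] = 3.0           # slice IDs 13..19
    return profile


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study's cohort structure: 72 class-0 (math) and 51
    class-1 (non-math) subjects, a 20-voxel VOI edge, 20 slices per subject.
    """

    n_math: int = 72
    n_nonmath: int = 51
    voi_edge: int = 20
    n_slices: int = 20
    effect_profile: np.ndarray | None = None
    noise_sd: float = 1.0
    background_sd: float = 0.5      # amplitude of the smooth background field
    background_smooth: float = 3.0  # gaussian smoothing sigma of the background, voxels
    blob_sigma: float = 3.0         # spatial extent of the class signal, voxels
    blob_center: tuple[float, float] = (12.0, 8.0)  # in-slice signal location
    seed: int = 0

    def __post_init__(self):
        if self.n_math < 0 or self.n_nonmath < 0:
            raise ValueError("subject counts must be non-negative")
        if self.voi_edge < 1 or self.n_slices < 1 or self.n_slices > self.voi_edge:
            raise ValueError("need 1 <= n_slices <= voi_edge and voi_edge >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_profile is None:
            self.effect_profile = default_effect_profile(self.n_slices)
        self.effect_profile = np.asarray(self.effect_profile, dtype=float)
        if self.effect_profile.shape != (self.n_slices,):
            raise ValueError(
                f"effect_profile must have length n_slices={self.n_slices}, "
                f"got {self.effect_profile.shape}"
            )
        if np.any(self.effect_profile < 0):
            raise ValueError("effect sizes must be >= 0")


@dataclass
class SubjectRecord:
    """One subject: identifier, binary group label and VOI intensity volume."""

    subject_id: str
    label: int          # 0 = math, 1 = non-math
    volume: np.ndarray  # (voi_edge, voi_edge, voi_edge) float intensities

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        self.volume = np.asarray(self.volume, dtype=float)
        if not np.all(np.isfinite(self.volume)):
            raise ValueError("volume must be finite")


def _signal_blob(edge: int, center: tuple[float, float], sigma: float) -> np.ndarray:
    """Unit-peak 2D Gaussian bump; the fixed spatial pattern of the class signal."""
    yy, xx = np.mgrid[0:edge, 0:edge]
    cy, cx = center
    return np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sigma**2))


def generate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Generate ``n_math + n_nonmath`` subjects, a pure function of the seed.

    Class-1 subjects receive an additive blob in every slice along axis 0,
    scaled by ``effect_profile[slice]``; both classes share the same
    background-field and noise distribution.
    """
    rng = np.random.default_rng(config.seed)
    edge = config.voi_edge
    blob = _signal_blob(edge, config.blob_center, config.blob_sigma)
    records: list[SubjectRecord] = []
    labels = [0] * config.n_math + [1] * config.n_nonmath
    for idx, label in enumerate(labels):
        background = ndimage.gaussian_filter(
            rng.normal(0.0, 1.0, size=(edge, edge, edge)), config.background_smooth
        )
        # smoothing shrinks the variance; rescale to the requested amplitude
        background *= config.background_sd / max(background.std(), 1e-12)
        volume = background + rng.normal(0.0, config.noise_sd, size=(edge, edge, edge))
        if label == 1:
            for k in range(config.n_slices):
                volume[k] += config.effect_profile[k] * blob
        records.append(SubjectRecord(subject_id=f"sub-{idx + 1:03d}", label=label, volume=volume))
    return records


def slice_count(cohort: list[SubjectRecord], n_slices: int = 20) -> int:
    """Total number of 2D slice instances the cohort yields (subjects x slices)."""
    return len(cohort) * n_slices


def write_cohort(cohort: list[SubjectRecord], out_dir, config: CohortConfig | None = None) -> "pd.DataFrame":
    """Write one NIfTI volume per subject plus a manifest CSV.

    The manifest has columns subject_id, label, path, cx, cy, cz where the
    center is the VOI-convention center voxel (edge//2 in each axis) so the
    volumes round-trip through the VOI-cropping reader unchanged.
    """
    import nibabel as nib
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        path = out_dir / f"{rec.subject_id}.nii"
        nib.save(nib.Nifti1Image(rec.volume, affine=np.eye(4)), path)
        c = rec.volume.shape[0] // 2
        rows.append(
            {"subject_id": rec.subject_id, "label": rec.label, "path": str(path), "cx": c, "cy": c, "cz": c}
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
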