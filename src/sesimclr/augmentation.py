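"""Stochastic view generation for contrastive training.

The two "views" of a slice are independent draws from one augmentation family
(the same family for both operators, by construction: a single config drives
both).  For single-channel 20x20 slices the family is random resized crop,
horizontal flip, multiplicative intensity jitter and optional Gaussian blur —
the SimCLR-style recipe with color transforms dropped as inapplicable.
Vertical flips are off by default since anatomical up/down carries meaning.

Augmentation is label-free: nothing here reads or writes labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentConfig", "sample_view", "make_pair", "identity_config"]


@dataclass(frozen=True)
class AugmentConfig:
    """Distributional parameters of the view-generating family.

    crop_scale_range: area fraction interval of the random resized crop.
    flip_prob: probability of a horizontal (left-right) flip.
    vflip_prob: probability of a vertical flip (0 by default).
    jitter_sd: SD of the multiplicative intensity gain (gain = 1 + N(0, sd)).
    blur_prob / blur_sigma_range: probability and sigma interval of a
        Gaussian blur.
    """

    crop_scale_range: tuple[float, float] = (0.6, 1.0)
    flip_prob: float = 0.5
    vflip_prob: float = 0.0
    jitter_sd: float = 0.1
    blur_prob: float = 0.0
    blur_sigma_range: tuple[float, float] = (0.3, 1.0)

    def __post_init__(self):
        lo, hi = self.crop_scale_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("crop_scale_range must lie within (0, 1]")
        for p in (self.flip_prob, self.vflip_prob, self.blur_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


def identity_config() -> AugmentConfig:
    """A degenerate family whose only member is the identity transform."""
    return AugmentConfig(crop_scale_range=(1.0, 1.0), flip_prob=0.0, vflip_prob=0.0,
                         jitter_sd=0.0, blur_prob=0.0)


def _bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = img.shape
    if (h, w) == (out_h, out_w):
        return img
    # align-corners sampling grid
    rows = np.linspace(0.0, h - 1.0, out_h)
    cols = np.linspace(0.0, w - 1.0, out_w)
    grid = np.meshgrid(rows, cols, indexing="ij")
    return ndimage.map_coordinates(img, grid, order=1, mode="nearest")


def sample_view(pixels: np.ndarray, config: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """One stochastic transform of a slice; same spatial shape as the input.

    Deterministic given the generator state; the transform distribution is
    fixed entirely by `config`.
    """
    img = np.asarray(pixels, dtype=float)
    h, w = img.shape

    # random resized crop (square, area-fraction parametrized)
    lo, hi = config.crop_scale_range
    scale = rng.uniform(lo, hi)
    side = max(1, int(round(min(h, w) * np.sqrt(scale))))
    top = rng.integers(0, h - side + 1)
    left = rng.integers(0, w - side + 1)
    out = img[top : top + side, left : left + side]
    out = _bilinear_resize(out, h, w)

    if rng.random() < config.flip_prob:
        out = out[:, ::-1]
    if rng.random() < config.vflip_prob:
        out = out[::-1, :]

    if config.jitter_sd > 0:
        out = out * (1.0 + rng.normal(0.0, config.jitter_sd))

    if config.blur_prob > 0 and rng.random() < config.blur_prob:
        sigma = rng.uniform(*config.blur_sigma_range)
        out = ndimage.gaussian_filter(out, sigma)

    return np.ascontiguousarray(out)


def make_pair(pixels: np.ndarray, config: AugmentConfig,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """The two augmented views of one instance, drawn from disjoint substreams."""
    stream_a, stream_b = rng.spawn(2)
    return sample_view(pixels, config, stream_a), sample_view(pixels, config, stream_b)
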