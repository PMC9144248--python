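"""Image conditioning: pad to square, center crop, anti-aliased downsampling,
and rotation augmentation.

Images go through the full chain (zero-pad -> center crop -> Gaussian
low-pass -> subsample); masks go through nearest-neighbor variants of the
same geometry (no low-pass, no interpolation) so integer labels are
preserved and the label set can never grow.

Conventions (documented tie-breaks): odd padding deficits put the extra
zero row/column at the bottom/right; odd crop remainders likewise remove
the extra row/column from the bottom/right; "crop by fraction f" means f
per linear dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._exceptions import ConfigurationError, DimensionError
from .phantom import LabeledSlice

__all__ = [
    "PreprocessConfig",
    "zero_pad_square",
    "center_crop",
    "lowpass_downsample",
    "preprocess_slice",
    "augment_rotation",
]


@dataclass(frozen=True)
class PreprocessConfig:
    target_size: int = 128
    crop_fraction: float = 0.5
    rotation_range_deg: tuple[float, float] = (-60.0, 60.0)

    def __post_init__(self):
        if not 0 < self.crop_fraction <= 1:
            raise ConfigurationError("crop_fraction must be in (0, 1]")
        if self.rotation_range_deg[0] > self.rotation_range_deg[1]:
            raise ConfigurationError("rotation range low > high")
        if self.target_size < 8:
            raise ConfigurationError("target_size must be >= 8")


def zero_pad_square(image: np.ndarray) -> np.ndarray:
    """Pad to S x S, S = max(H, W), content centered, new pixels zero."""
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise DimensionError("zero_pad_square expects a nonempty 2D array")
    h, w = image.shape
    s = max(h, w)
    if h == w:
        return image
    py, px = s - h, s - w
    return np.pad(image, ((py // 2, py - py // 2), (px // 2, px - px // 2)))


def center_crop(image: np.ndarray, fraction: float) -> np.ndarray:
    """Centered crop to round(fraction * S) per side of a square image."""
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise DimensionError("center_crop expects a square 2D array")
    s = image.shape[0]
    size = int(round(fraction * s))
    if size < 2:
        raise DimensionError(f"crop of {s} by {fraction} would be smaller than 2x2")
    start = (s - size) // 2
    return image[start : start + size, start : start + size]


def _subsample_indices(n_in: int, n_out: int) -> np.ndarray:
    return np.round(np.arange(n_out) * n_in / n_out).astype(int)


def lowpass_downsample(image: np.ndarray, target_size: int) -> np.ndarray:
    """Gaussian anti-aliasing filter then uniform subsampling.

    sigma = 0.6 * (input_size / target_size), strong enough that a unit
    impulse keeps 1/factor^2 of its energy after decimation to within 2%
    at any sampling phase; a unit ratio bypasses the filter entirely and
    returns the input unchanged.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise DimensionError("lowpass_downsample expects a square 2D array")
    s = image.shape[0]
    if s < target_size:
        raise DimensionError(f"cannot downsample {s} to larger size {target_size}")
    if s == target_size:
        return image
    sigma = 0.6 * (s / target_size)
    smoothed = ndimage.gaussian_filter(image.astype(float), sigma, mode="nearest")
    idx = _subsample_indices(s, target_size)
    return smoothed[np.ix_(idx, idx)]


def _nearest_downsample(mask: np.ndarray, target_size: int) -> np.ndarray:
    s = mask.shape[0]
    if s == target_size:
        return mask
    idx = _subsample_indices(s, target_size)
    return mask[np.ix_(idx, idx)]


def preprocess_slice(slc: LabeledSlice, config: PreprocessConfig) -> LabeledSlice:
    """Run the full conditioning chain on image and mask."""
    img = zero_pad_square(slc.image)
    img = center_crop(img, config.crop_fraction)
    if img.shape[0] < config.target_size:
        raise DimensionError(
            f"cropped size {img.shape[0]} below target {config.target_size}"
        )
    img = lowpass_downsample(img, config.target_size)

    msk = zero_pad_square(slc.mask)
    msk = center_crop(msk, config.crop_fraction)
    msk = _nearest_downsample(msk, config.target_size)
    return LabeledSlice(np.asarray(img), np.asarray(msk))


def augment_rotation(
    slc: LabeledSlice,
    angle_deg: float,
    rotation_range_deg: tuple[float, float] = (-60.0, 60.0),
) -> LabeledSlice:
    """Rotate about the image center: bilinear for the image (zero fill),
    nearest-neighbor for the mask. Shapes are preserved."""
    lo, hi = rotation_range_deg
    if not lo <= angle_deg <= hi:
        raise ConfigurationError(
            f"angle {angle_deg} outside configured range [{lo}, {hi}]"
        )
    if angle_deg == 0:
        return LabeledSlice(slc.image.copy(), slc.mask.copy())
    img = ndimage.rotate(
        slc.image.astype(float), angle_deg, reshape=False, order=1,
        mode="constant", cval=0.0,
    )
    msk = ndimage.rotate(
        slc.mask, angle_deg, reshape=False, order=0, mode="constant", cval=0
    )
    return LabeledSlice(img, msk)
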