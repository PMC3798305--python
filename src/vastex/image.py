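"""Gray-level image container, ROI extraction and quantization.

Conventions: pixels are stored row-major as ``(row, col)`` with 0-based
indices; an ROI is the half-open block ``[y0, y0+h) x [x0, x0+w)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grid of integer gray levels in ``[0, levels - 1]``.

    Parameters
    ----------
    pixels
        2-D integer array of gray values.
    levels
        Number of possible gray values L (>= 2).  Pixel values must lie in
        ``[0, levels - 1]``; for 8-bit images ``levels`` is 256.
    """

    pixels: np.ndarray
    levels: int = 256

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {arr.shape}")
        if arr.shape[0] < 2 or arr.shape[1] < 2:
            raise ValueError(f"image must be at least 2x2, got {arr.shape}")
        if self.levels < 2:
            raise ValueError(f"levels must be >= 2, got {self.levels}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("pixel values must be integers")
        arr = arr.astype(np.int64)  # avoid overflow in downstream index math
        if arr.min() < 0 or arr.max() >= self.levels:
            raise ValueError(
                f"pixel values must lie in [0, {self.levels - 1}], "
                f"got range [{arr.min()}, {arr.max()}]"
            )
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def astype_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64)


@dataclass(frozen=True)
class RoiSpec:
    """Rectangular region of interest: top-left corner plus size in pixels."""

    x0: int
    y0: int
    width: int
    height: int

    MIN_SIZE = 8  # smallest size at which all families (d=2, displacement 3) exist

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")
        if self.width < self.MIN_SIZE or self.height < self.MIN_SIZE:
            raise ValueError(
                f"ROI must be at least {self.MIN_SIZE}x{self.MIN_SIZE}, "
                f"got {self.width}x{self.height}"
            )


def load_gray_image(path) -> GrayImage:
    """Load an 8-bit PNG/TIFF as a :class:`GrayImage` with L = 256.

    Multi-channel images are collapsed to gray by the channel mean.
    """
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if arr.ndim == 3:
        arr = arr[..., :3].astype(np.float64).mean(axis=2)
        arr = np.round(arr).astype(np.int64)
    return GrayImage(arr.astype(np.int64), levels=256)


def save_gray_image(image: GrayImage, path) -> None:
    """Write an image (L must be <= 256) as an 8-bit grayscale file."""
    if image.levels > 256:
        raise ValueError("only 8-bit output supported")
    Image.fromarray(image.pixels.astype(np.uint8), mode="L").save(path)


def extract_roi(image: GrayImage, roi: RoiSpec) -> GrayImage:
    """Copy the ROI sub-grid out of ``image``; gray-level count is unchanged."""
    h, w = image.shape
    if roi.y0 + roi.height > h or roi.x0 + roi.width > w:
        raise ValueError(
            f"ROI {roi} exceeds image bounds {h}x{w}"
        )
    sub = image.pixels[roi.y0:roi.y0 + roi.height, roi.x0:roi.x0 + roi.width]
    return GrayImage(sub.copy(), levels=image.levels)


def quantize(image: GrayImage, target_levels: int) -> GrayImage:
    """Reduce the gray-level count by the monotone map q = floor(p * T / L)."""
    if target_levels < 2:
        raise ValueError(f"target_levels must be >= 2, got {target_levels}")
    if target_levels > image.levels:
        raise ValueError(
            f"target_levels {target_levels} exceeds image levels {image.levels}"
        )
    if target_levels == image.levels:
        return image
    q = (image.pixels * target_levels) // image.levels
    return GrayImage(q, levels=target_levels)
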