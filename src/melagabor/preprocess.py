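"""Image loading, standardization, denoising and contrast enhancement.

Dermoscopy images arrive at arbitrary resolution (PH2 images are
768x560); every downstream stage assumes a fixed 256x256 RGB raster, so
loading and resizing live here, together with grayscale conversion,
Gaussian smoothing and global histogram equalization.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage

#: side length of the standardized raster, in pixels
STANDARD_SIZE = 256

#: ITU-R BT.601 luma weights for RGB -> gray conversion
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class DecodeError(ValueError):
    """Raised when an image file cannot be read or decoded."""


@dataclasses.dataclass
class DermoscopyImage:
    """A standardized 8-bit RGB dermoscopy raster plus provenance.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    source_path : origin of the raster, "" for in-memory images
    label : 0 = benign, 1 = malignant, None = unknown
    """

    pixels: np.ndarray
    source_path: str = ""
    label: Optional[int] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("DermoscopyImage requires an HxWx3 raster")
        if self.pixels.dtype != np.uint8:
            raise ValueError("DermoscopyImage requires 8-bit channels")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _round_half_up(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (for x >= 0)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def standardize(path, size: int = STANDARD_SIZE,
                label: Optional[int] = None) -> DermoscopyImage:
    """Load an image file and resample it to the standard RGB grid.

    Grayscale sources are replicated across the three channels; aspect
    ratio is not preserved (plain bilinear resampling to ``size x size``).
    An already-standard input is passed through pixel-identically.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im = im.convert("RGB")
            if im.size != (size, size):
                if im.size[0] == 0 or im.size[1] == 0:
                    raise DecodeError(f"zero-area image: {path}")
                im = im.resize((size, size), Image.BILINEAR)
            pixels = np.asarray(im, dtype=np.uint8)
    except (UnidentifiedImageError, OSError) as exc:
        raise DecodeError(f"cannot decode image file {path}: {exc}") from exc
    if pixels.size == 0:
        raise DecodeError(f"zero-area image: {path}")
    return DermoscopyImage(pixels=pixels, source_path=str(path), label=label)


def to_grayscale(img) -> np.ndarray:
    """Convert an RGB raster to 8-bit gray with BT.601 luma weights.

    Accepts a :class:`DermoscopyImage` or a bare HxWx3 array; rounding
    is half-up so a uniform (v, v, v) pixel maps exactly to v.
    """
    pixels = img.pixels if isinstance(img, DermoscopyImage) else np.asarray(img)
    luma = pixels[..., 0] * LUMA_WEIGHTS[0] \
        + pixels[..., 1] * LUMA_WEIGHTS[1] \
        + pixels[..., 2] * LUMA_WEIGHTS[2]
    return _round_half_up(luma).clip(0, 255).astype(np.uint8)


def smooth(gray: np.ndarray, kernel_size: int = 5,
           sigma: float = 1.0) -> np.ndarray:
    """Gaussian smoothing with reflective borders.

    ``kernel_size`` must be odd and >= 3; it fixes the spatial support of
    the truncated Gaussian (sigma defaults to 1.0).
    """
    if kernel_size % 2 == 0 or kernel_size < 3:
        raise ValueError(f"kernel_size must be odd and >= 3, got {kernel_size}")
    radius = (kernel_size - 1) // 2
    out = ndimage.gaussian_filter(np.asarray(gray, dtype=float), sigma=sigma,
                                  mode="reflect", truncate=radius / sigma)
    return _round_half_up(out).clip(0, 255).astype(np.uint8)


def equalize(gray: np.ndarray) -> np.ndarray:
    """Global histogram equalization over the 256 intensity levels.

    Uses the classic cumulative-histogram mapping
    ``L(v) = round((cdf(v) - cdf_min) / (N - cdf_min) * 255)``, which is
    monotone non-decreasing and leaves a constant image untouched
    (degenerate single-level histogram).
    """
    gray = np.asarray(gray, dtype=np.uint8)
    mapping = equalization_map(np.bincount(gray.ravel(), minlength=256))
    return mapping[gray]


def equalization_map(histogram: np.ndarray) -> np.ndarray:
    """The 256-entry level mapping used by :func:`equalize`."""
    hist = np.asarray(histogram, dtype=np.int64)
    cdf = np.cumsum(hist)
    total = int(cdf[-1])
    nonzero = cdf[hist > 0]
    cdf_min = int(nonzero[0]) if nonzero.size else 0
    if total == cdf_min:  # single occupied level: identity mapping
        return np.arange(256, dtype=np.uint8)
    scaled = (cdf - cdf_min) / (total - cdf_min) * 255.0
    return _round_half_up(np.maximum(scaled, 0.0)).astype(np.uint8)
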