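"""Grayscale conversion and median-model background subtraction.

Brightfield co-culture frames carry uneven illumination and dense
immune-cell background.  The working image for all downstream stages is a
single-channel, floating-point residual: the grayscale frame minus a
median-filter background model, clipped at zero.  Organoid membranes —
thin, locally bright ridges — survive this subtraction; smooth background
and broad illumination gradients do not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from skimage.filters import rank

from .core_io import Calibration, RasterImage
from .errors import FormatError, ParameterError

#: ITU-R 601 luma weights for RGB → grayscale reduction.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class GrayImage:
    """Single-channel working image on a floating 0..max_value scale."""

    pixels: np.ndarray
    calibration: Calibration
    max_value: float = 255.0

    def __post_init__(self):
        if self.pixels.ndim != 2:
            raise FormatError("GrayImage must be single-channel 2D")
        self.pixels = np.asarray(self.pixels, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def to_grayscale(image: RasterImage) -> GrayImage:
    """Reduce an imported frame to a virtual grayscale channel.

    RGB is reduced with luma weights (0.299, 0.587, 0.114); single-channel
    input passes through.  Output stays on the input's intensity scale.
    """
    if image.channels == 1:
        gray = image.pixels.astype(np.float64)
    elif image.channels == 3:
        w = np.asarray(LUMA_WEIGHTS)
        gray = image.pixels.astype(np.float64) @ w
    else:
        raise FormatError(f"expected 1 or 3 channels, got {image.channels}")
    return GrayImage(pixels=gray, calibration=image.calibration,
                     max_value=float(image.max_value))


def _windowed_median(px: np.ndarray, radius_px: int) -> np.ndarray:
    """Exact square-window median with reflective borders.

    Integer-valued images take the O(1)-per-pixel sliding-histogram rank
    filter on a reflect-padded copy (identical result to the direct
    windowed median); general float images fall back to the direct filter.
    """
    size = 2 * radius_px + 1
    rounded = np.rint(px)
    if np.array_equal(rounded, px) and px.min() >= 0 and px.max() <= 65535:
        dtype = np.uint8 if px.max() <= 255 else np.uint16
        padded = np.pad(rounded.astype(dtype), radius_px, mode="symmetric")
        med = rank.median(padded, np.ones((size, size), dtype=bool))
        return med[radius_px:-radius_px, radius_px:-radius_px].astype(np.float64)
    return median_filter(px, size=size, mode="reflect")


def subtract_background(image: GrayImage, radius_px: int) -> GrayImage:
    """Subtract a windowed-median background model, clipping negatives at 0.

    The window is a square of side ``2·radius_px + 1`` with reflective
    borders.  The radius must exceed the expected membrane half-width so
    the model does not absorb the ridges themselves.
    """
    if radius_px < 1:
        raise ParameterError(f"radius_px must be >= 1, got {radius_px}")
    h, w = image.shape
    if 2 * radius_px + 1 > min(h, w):
        raise ParameterError(
            f"background window {2 * radius_px + 1} exceeds image extent {min(h, w)}"
        )
    model = _windowed_median(image.pixels, radius_px)
    residual = np.clip(image.pixels - model, 0.0, None)
    return GrayImage(pixels=residual, calibration=image.calibration,
                     max_value=image.max_value)
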