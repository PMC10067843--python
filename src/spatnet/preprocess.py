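"""Intensity quality control: background subtraction, percentile rescaling,
Otsu thresholding, best-focus selection and translational registration.

The canonical per-channel order used by the pipeline is rolling-ball
background subtraction first, then percentile rescaling to [0, 1], then Otsu
foreground masking; each step is also independently callable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation

from .exceptions import DegenerateInputError, DimensionError, ValidationError
from .model import BinaryMask, ChannelImage

OTSU_BINS = 256


@dataclass(frozen=True)
class RescaleParams:
    """Intensities at the low/high percentiles used for rescaling."""

    low_value: float
    high_value: float

    def __post_init__(self) -> None:
        if not self.high_value > self.low_value:
            raise DegenerateInputError(
                f"high_value ({self.high_value}) must exceed low_value ({self.low_value})"
            )


def rescale_percentile(
    image: ChannelImage,
    mask: BinaryMask,
    low: float = 20.0,
    high: float = 99.9,
) -> tuple[ChannelImage, RescaleParams]:
    """Clip-and-rescale intensities to [0, 1] between two mask percentiles.

    The low percentile (default 20, background pixels) maps to 0 and the high
    percentile (default 99.9, saturated pixels) maps to 1; values outside are
    clipped and pixels outside the mask are set to 0.  Percentiles use the
    linear-interpolation definition and are computed over mask pixels only.
    """
    if image.shape != mask.shape:
        raise DimensionError(f"image {image.shape} vs mask {mask.shape}")
    if mask.area == 0:
        raise ValidationError("mask is empty")
    if not low < high:
        raise ValidationError(f"need low < high, got ({low}, {high})")
    values = image.pixels[mask.pixels]
    low_value, high_value = np.percentile(values, [low, high], method="linear")
    if high_value == low_value:
        raise DegenerateInputError(
            f"percentiles coincide at {low_value}; region is (near-)constant"
        )
    params = RescaleParams(float(low_value), float(high_value))
    scaled = np.clip((image.pixels - params.low_value) / (params.high_value - params.low_value), 0.0, 1.0)
    scaled[~mask.pixels] = 0.0
    return image.with_pixels(scaled), params


def rolling_ball_subtract(image: ChannelImage, radius_px: float) -> ChannelImage:
    """Subtract a rolling-ball background estimate.

    The background is the grayscale morphological opening of the image by a
    disk of the given radius, so any structure narrower than the disk
    survives the subtraction while broad background shading is removed.  The
    output is non-negative by construction (opening never exceeds the image).
    """
    if radius_px < 1:
        raise ValidationError(f"radius_px must be >= 1, got {radius_px}")
    footprint = disk(int(round(radius_px)))
    background = ndimage.grey_opening(image.pixels, footprint=footprint)
    return image.with_pixels(np.clip(image.pixels - background, 0.0, None))


def otsu_threshold(image: ChannelImage, mask: BinaryMask) -> tuple[float, BinaryMask]:
    """Otsu's threshold over a 256-bin histogram of mask-interior values.

    Returns the threshold (in original intensity units) maximizing the
    between-class variance, plus the foreground mask ``mask & (image >
    threshold)``.  A constant region is a degenerate input.
    """
    if image.shape != mask.shape:
        raise DimensionError(f"image {image.shape} vs mask {mask.shape}")
    if mask.area == 0:
        raise ValidationError("mask is empty")
    values = image.pixels[mask.pixels]
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise DegenerateInputError("all mask pixels are equal; Otsu threshold undefined")
    stretched = (values - vmin) / (vmax - vmin)
    counts, edges = np.histogram(stretched, bins=OTSU_BINS, range=(0.0, 1.0))
    # between-class variance for every split "bin <= t vs bin > t"
    w = counts.astype(np.float64)
    total = w.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    cum_w = np.cumsum(w)[:-1]
    cum_m = np.cumsum(w * centers)[:-1]
    mean_all = (w * centers).sum() / total
    with np.errstate(invalid="ignore", divide="ignore"):
        p0 = cum_w / total
        mu0 = cum_m / cum_w
        mu1 = ((w * centers).sum() - cum_m) / (total - cum_w)
        var_between = p0 * (1.0 - p0) * (mu0 - mu1) ** 2
    var_between = np.nan_to_num(var_between, nan=-np.inf)
    best = int(np.argmax(var_between))  # ties -> lowest split
    threshold = vmin + edges[best + 1] * (vmax - vmin)
    del mean_all
    foreground = BinaryMask(mask.pixels & (image.pixels > threshold))
    return float(threshold), foreground


def focus_score(pixels: np.ndarray) -> float:
    """Variance of the Laplacian response: the sharper, the larger."""
    lap = ndimage.laplace(np.asarray(pixels, dtype=np.float64), mode="reflect")
    return float(lap.var())


def best_focus_slice(zstack: Sequence[ChannelImage]) -> int:
    """Index of the sharpest slice by variance-of-Laplacian; ties -> lowest."""
    if len(zstack) == 0:
        raise ValidationError("z-stack is empty")
    shapes = {img.shape for img in zstack}
    if len(shapes) != 1:
        raise DimensionError(f"z-stack slices have mixed shapes: {shapes}")
    scores = np.array([focus_score(img.pixels) for img in zstack])
    return int(np.argmax(scores))


def register_translation(reference: ChannelImage, moving: ChannelImage) -> tuple[int, int]:
    """Integer (row, col) displacement of ``moving`` relative to ``reference``.

    Found by phase correlation; if ``moving`` is ``reference`` rolled by
    ``(dr, dc)`` the return value is ``(dr, dc)``, and applying the negated
    shift re-aligns the pair.  Shifts are reported in the centered range
    ``(-H/2, H/2] x (-W/2, W/2]``.
    """
    if reference.shape != moving.shape:
        raise DimensionError(f"reference {reference.shape} vs moving {moving.shape}")
    shift, _error, _phase = phase_cross_correlation(
        reference.pixels, moving.pixels, upsample_factor=1, normalization=None
    )
    # phase_cross_correlation returns the correction to apply to `moving`;
    # the displacement of `moving` is its negation
    return (-int(round(shift[0])), -int(round(shift[1])))
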