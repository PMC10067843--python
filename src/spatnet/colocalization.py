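"""Per-cell marker-pair colocalization metrics.

Two complementary metrics quantify the spatial co-occurrence of a marker
pair within one cell:

* Pearson correlation of the raw paired intensities over all cell-mask
  pixels (intensity-based, threshold-free);
* pixel-overlap fraction ``|A & B| / (|A| + |B|)`` of the two Otsu
  foreground masks, so disjoint markers score 0 and identical masks
  saturate at 0.5.  A Jaccard-style denominator ``|A | B|`` is available
  behind a switch.

Scatter samples reproduce the intensity scatterplots: up to ``n`` mask
pixels are drawn without replacement, min-max scaled per channel and
weighted by a 2D Gaussian kernel density estimate for density coloring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import gaussian_kde

from .exceptions import DegenerateInputError, DimensionError, ValidationError
from .model import BinaryMask, ChannelImage, MarkerSummaryRow

#: 3x3 square (8-connectivity) structuring element for area opening/closing;
#: removes isolated pixels while leaving solid convex shapes untouched.
SQUARE3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class ScatterSample:
    """Paired, min-max scaled intensity sample with KDE density weights."""

    marker_a: str
    marker_b: str
    values: np.ndarray  # (n, 2) in [0, 1]
    density: np.ndarray  # (n,), >= 0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        density = np.asarray(self.density, dtype=np.float64)
        if values.ndim != 2 or values.shape[1] != 2:
            raise DimensionError(f"values must be (n, 2), got {values.shape}")
        if density.shape != (values.shape[0],):
            raise DimensionError("density must have one weight per sample point")
        if values.size and (values.min() < 0 or values.max() > 1 + 1e-12):
            raise ValidationError("scatter values must lie in [0, 1]")
        if density.size and density.min() < 0:
            raise ValidationError("density weights must be >= 0")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "density", density)

    def __len__(self) -> int:
        return int(self.values.shape[0])


def pearson_pair(image_a: ChannelImage, image_b: ChannelImage, mask: BinaryMask) -> float:
    """Sample Pearson correlation of two channels over the mask pixels."""
    if image_a.shape != image_b.shape or image_a.shape != mask.shape:
        raise DimensionError(
            f"shapes differ: {image_a.shape}, {image_b.shape}, mask {mask.shape}"
        )
    if mask.area < 2:
        raise ValidationError("mask must contain at least 2 pixels")
    a = image_a.pixels[mask.pixels]
    b = image_b.pixels[mask.pixels]
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum() * (db * db).sum())
    if denom == 0.0:
        raise DegenerateInputError(
            f"constant channel within mask ({image_a.marker_name} vs {image_b.marker_name}); "
            "Pearson correlation undefined"
        )
    r = float((da * db).sum() / denom)
    return min(1.0, max(-1.0, r))


def pixel_overlap(
    mask_a: BinaryMask, mask_b: BinaryMask, denominator: str = "sum"
) -> float:
    """Fraction of overlapping foreground pixels.

    With the default ``"sum"`` denominator the metric is
    ``|A & B| / (|A| + |B|)`` with range [0, 0.5]; ``"union"`` gives the
    Jaccard index ``|A & B| / |A | B|`` with range [0, 1].
    """
    if mask_a.shape != mask_b.shape:
        raise DimensionError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    n_a, n_b = mask_a.area, mask_b.area
    if n_a + n_b == 0:
        raise DegenerateInputError("both masks are empty; overlap undefined")
    inter = int(np.count_nonzero(mask_a.pixels & mask_b.pixels))
    if denominator == "sum":
        return inter / (n_a + n_b)
    if denominator == "union":
        return inter / (n_a + n_b - inter)
    raise ValidationError(f"denominator must be 'sum' or 'union', got {denominator!r}")


def _minmax_scale_column(values: np.ndarray) -> np.ndarray:
    vmin, vmax = values.min(), values.max()
    if vmax == vmin:
        return np.zeros_like(values)
    return (values - vmin) / (vmax - vmin)


def sample_intensity_pairs(
    image_a: ChannelImage,
    image_b: ChannelImage,
    mask: BinaryMask,
    n: int,
    seed: int,
    kde_max_train: int = 2000,
) -> ScatterSample:
    """Draw up to ``n`` mask pixels and attach Gaussian-KDE density weights.

    Sampling is uniform without replacement (capped at the mask population),
    per-channel min-max scaling is computed over the sample, and density
    weights come from a Scott's-rule Gaussian KDE of the 2D sample.  For
    samples larger than ``kde_max_train`` the KDE is fitted on a seeded
    subsample and evaluated at every point, which keeps density coloring
    tractable at the 50,000-pixel scale.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if image_a.shape != image_b.shape or image_a.shape != mask.shape:
        raise DimensionError(
            f"shapes differ: {image_a.shape}, {image_b.shape}, mask {mask.shape}"
        )
    if mask.area == 0:
        raise ValidationError("mask is empty")
    rng = np.random.default_rng(seed)
    a_all = image_a.pixels[mask.pixels]
    b_all = image_b.pixels[mask.pixels]
    m = min(n, a_all.size)
    idx = rng.choice(a_all.size, size=m, replace=False)
    sample = np.column_stack([_minmax_scale_column(a_all[idx]), _minmax_scale_column(b_all[idx])])
    density = _kde_density(sample, rng, kde_max_train)
    return ScatterSample(
        marker_a=image_a.marker_name, marker_b=image_b.marker_name,
        values=sample, density=density,
    )


def sample_intensity_pairs_pooled(
    values_a: np.ndarray,
    values_b: np.ndarray,
    marker_a: str,
    marker_b: str,
    n: int,
    seed: int,
    kde_max_train: int = 2000,
) -> ScatterSample:
    """Scatter sample from already pooled paired intensity values.

    Used when one scatterplot pools the mask pixels of several cells:
    pooling precedes sampling, then the same without-replacement draw,
    min-max scaling and KDE weighting as :func:`sample_intensity_pairs`.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    a_all = np.asarray(values_a, dtype=np.float64).ravel()
    b_all = np.asarray(values_b, dtype=np.float64).ravel()
    if a_all.size != b_all.size:
        raise DimensionError("paired value arrays must have equal length")
    if a_all.size == 0:
        raise ValidationError("no pixels to sample from")
    rng = np.random.default_rng(seed)
    m = min(n, a_all.size)
    idx = rng.choice(a_all.size, size=m, replace=False)
    sample = np.column_stack([_minmax_scale_column(a_all[idx]), _minmax_scale_column(b_all[idx])])
    density = _kde_density(sample, rng, kde_max_train)
    return ScatterSample(marker_a=marker_a, marker_b=marker_b, values=sample, density=density)


def _kde_density(sample: np.ndarray, rng: np.random.Generator, kde_max_train: int) -> np.ndarray:
    """Gaussian-KDE density at every sample point, robust to singular spreads."""
    m = sample.shape[0]
    if m < 3:
        return np.ones(m)
    train = sample
    if m > kde_max_train:
        train = sample[rng.choice(m, size=kde_max_train, replace=False)]
    try:
        kde = gaussian_kde(train.T)  # Scott's rule bandwidth
        return np.clip(kde(sample.T), 0.0, None)
    except np.linalg.LinAlgError:
        # perfectly collinear sample: jitter the training set minutely
        jitter = rng.normal(0.0, 1e-9, size=train.shape)
        kde = gaussian_kde((train + jitter).T)
        return np.clip(kde(sample.T), 0.0, None)


def marker_area_intensity(
    image: ChannelImage,
    foreground: BinaryMask,
    cell_mask: BinaryMask,
    cell_id: str = "",
) -> MarkerSummaryRow:
    """Per-marker area (after 3x3 opening then closing) and mean intensity.

    Opening removes isolated foreground pixels, closing fills pinholes; the
    remaining foreground pixel count is the marker area, converted to um^2
    via the squared pixel size.  Mean intensity is taken over the whole cell
    mask, matching per-cell marker expression summaries.
    """
    if image.shape != foreground.shape or image.shape != cell_mask.shape:
        raise DimensionError(
            f"shapes differ: image {image.shape}, foreground {foreground.shape}, "
            f"cell_mask {cell_mask.shape}"
        )
    if cell_mask.area == 0:
        raise ValidationError("cell_mask is empty")
    opened = ndimage.binary_opening(foreground.pixels, structure=SQUARE3)
    cleaned = ndimage.binary_closing(opened, structure=SQUARE3)
    area_px = int(np.count_nonzero(cleaned))
    return MarkerSummaryRow(
        cell_id=cell_id,
        marker=image.marker_name,
        area_px=area_px,
        area_um2=area_px * image.pixel_size_um**2,
        mean_intensity=float(image.pixels[cell_mask.pixels].mean()),
    )
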