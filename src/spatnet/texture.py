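"""Superpixel segmentation and focus-measure texture features.

Each marker image is partitioned into ~250 superpixels by spatially
regularized K-Means (SLIC) restricted to the cell mask, and six classic
focus-measure functionals are aggregated per superpixel:

* ``pixel_intensity`` - mean intensity;
* ``energy_laplacian`` - mean squared 4-neighbor Laplacian response;
* ``modified_laplacian`` - mean sum-modified-Laplacian ``|I*kx| + |I*ky|``
  with the (-1, 2, -1) row kernel and its transpose;
* ``diagonal_laplacian`` - the modified Laplacian plus the two diagonal
  (-1, 2, -1) kernels scaled by 1/sqrt(2), all four absolute responses
  summed;
* ``variance_laplacian`` - mean squared deviation of the Laplacian response
  from its cell-mask mean;
* ``gray_level_variance`` - mean squared deviation of the intensity from its
  cell-mask mean.

Aggregation is the mean, so features are independent of superpixel area, and
each feature column is additionally min-max normalized to [0, 1] across the
superpixels of the cell for heatmap display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.segmentation import slic

from .exceptions import DimensionError, ValidationError
from .model import BinaryMask, ChannelImage

FEATURE_COLUMNS = (
    "pixel_intensity",
    "energy_laplacian",
    "modified_laplacian",
    "diagonal_laplacian",
    "variance_laplacian",
    "gray_level_variance",
)

_K_STANDARD = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=np.float64)
_K_ROW = np.array([[-1, 2, -1]], dtype=np.float64)  # differences along columns
_K_COL = _K_ROW.T
_K_DIAG_MAIN = np.array([[-1, 0, 0], [0, 2, 0], [0, 0, -1]], dtype=np.float64) / math.sqrt(2)
_K_DIAG_ANTI = np.array([[0, 0, -1], [0, 2, 0], [-1, 0, 0]], dtype=np.float64) / math.sqrt(2)


@dataclass(frozen=True)
class SuperpixelMap:
    """Partition of a cell mask into superpixels labeled 1..m (0 outside)."""

    label_image: np.ndarray
    target_n: int

    def __post_init__(self) -> None:
        labels = np.asarray(self.label_image)
        if labels.ndim != 2:
            raise DimensionError(f"label_image must be 2D, got shape {labels.shape}")
        if labels.min() < 0:
            raise ValidationError("labels must be >= 0")
        m = int(labels.max())
        present = np.unique(labels[labels > 0])
        if m and (present.size != m or present[0] != 1 or present[-1] != m):
            raise ValidationError("superpixel labels must be contiguous 1..m")
        if m > self.target_n:
            raise ValidationError(f"realized {m} superpixels exceed target {self.target_n}")
        object.__setattr__(self, "label_image", labels.astype(np.int32))

    @property
    def m(self) -> int:
        """Realized superpixel count."""
        return int(self.label_image.max())

    @property
    def mask(self) -> np.ndarray:
        return self.label_image > 0


@dataclass(frozen=True)
class TextureTable:
    """Raw and min-max normalized texture features, one row per superpixel."""

    marker: str
    features: pd.DataFrame
    normalized: pd.DataFrame


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    present = np.unique(labels[labels > 0])
    lut = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    lut[present] = np.arange(1, present.size + 1, dtype=np.int32)
    return lut[labels]


def _merge_excess(labels: np.ndarray, target_n: int) -> np.ndarray:
    """Merge smallest superpixels into their dominant neighbor until m <= target."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        if ids.size <= target_n:
            break
        victim = ids[np.argmin(counts)]
        region = labels == victim
        ring = ndimage.binary_dilation(region) & ~region
        neighbors = labels[ring]
        neighbors = neighbors[neighbors > 0]
        if neighbors.size:
            n_ids, n_counts = np.unique(neighbors, return_counts=True)
            labels[region] = n_ids[np.argmax(n_counts)]
        else:  # detached islet: hand it to the largest region
            labels[region] = ids[np.argmax(counts)]
    return _relabel_contiguous(labels)


def superpixel_segment(
    image: ChannelImage,
    mask: BinaryMask,
    target_n: int,
    seed: Optional[int] = None,
    compactness: float = 0.1,
) -> SuperpixelMap:
    """SLIC superpixels of one marker restricted to the cell mask.

    Spatially regularized K-Means in (row, col, intensity) space on the
    min-max scaled image; the ``compactness`` weight trades spatial
    regularity against intensity homogeneity.  Labels are contiguous 1..m
    with ``m <= target_n`` (small excess regions produced by the
    connectivity cleanup are merged into their dominant neighbor).  The
    algorithm is deterministic; ``seed`` is accepted for interface
    uniformity.
    """
    del seed
    if image.shape != mask.shape:
        raise DimensionError(f"image {image.shape} vs mask {mask.shape}")
    if mask.area == 0:
        raise ValidationError("mask is empty")
    if target_n < 1:
        raise ValidationError(f"target_n must be >= 1, got {target_n}")
    if target_n > mask.area:
        raise ValidationError(f"target_n={target_n} exceeds mask pixel count {mask.area}")
    if target_n == 1:
        return SuperpixelMap(mask.pixels.astype(np.int32), target_n=1)
    vals = image.pixels[mask.pixels]
    vmin, vmax = vals.min(), vals.max()
    scaled = np.zeros_like(image.pixels)
    if vmax > vmin:
        scaled[mask.pixels] = (vals - vmin) / (vmax - vmin)
    labels = slic(
        scaled,
        n_segments=target_n,
        compactness=compactness,
        mask=mask.pixels,
        start_label=1,
        channel_axis=None,
        enforce_connectivity=True,
    )
    labels = _relabel_contiguous(labels.astype(np.int32))
    if labels.max() > target_n:
        labels = _merge_excess(labels, target_n)
    return SuperpixelMap(labels, target_n=target_n)


def laplacian_response(image: ChannelImage, variant: str = "standard") -> np.ndarray:
    """Laplacian response image with reflective boundary handling.

    ``standard`` convolves with the 4-neighbor Laplacian kernel; ``modified``
    returns ``|I*kx| + |I*ky|`` (sum-modified-Laplacian); ``diagonal`` adds
    the two 1/sqrt(2)-scaled diagonal kernels, summing all four absolute
    responses.
    """
    if image.shape[0] < 3 or image.shape[1] < 3:
        raise ValidationError(f"image must be at least 3x3, got {image.shape}")
    pixels = image.pixels

    def conv(kernel: np.ndarray) -> np.ndarray:
        return ndimage.convolve(pixels, kernel, mode="reflect")

    if variant == "standard":
        return conv(_K_STANDARD)
    if variant == "modified":
        return np.abs(conv(_K_ROW)) + np.abs(conv(_K_COL))
    if variant == "diagonal":
        return (
            np.abs(conv(_K_ROW))
            + np.abs(conv(_K_COL))
            + np.abs(conv(_K_DIAG_MAIN))
            + np.abs(conv(_K_DIAG_ANTI))
        )
    raise ValidationError(f"unknown variant {variant!r}")


def _minmax_columns(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    for col in out.columns:
        vmin, vmax = out[col].min(), out[col].max()
        out[col] = 0.0 if vmax == vmin else (out[col] - vmin) / (vmax - vmin)
    return out


def texture_features(
    image: ChannelImage,
    spmap: SuperpixelMap,
    reference: str = "mask",
) -> TextureTable:
    """Six texture features per superpixel, raw plus min-max normalized.

    The deviation-based features (``variance_laplacian``,
    ``gray_level_variance``) measure spread around the cell-mask-wide mean by
    default, so their area-weighted average over superpixels equals the
    mask-wide variance exactly; ``reference="superpixel"`` switches to
    per-superpixel means.
    """
    if image.shape != spmap.label_image.shape:
        raise DimensionError(f"image {image.shape} vs superpixel map {spmap.label_image.shape}")
    if reference not in ("mask", "superpixel"):
        raise ValidationError(f"reference must be 'mask' or 'superpixel', got {reference!r}")
    labels = spmap.label_image
    index = np.arange(1, spmap.m + 1)
    if index.size == 0:
        raise ValidationError("superpixel map is empty")
    mask = spmap.mask
    lap = laplacian_response(image, "standard")
    modified = laplacian_response(image, "modified")
    diagonal = laplacian_response(image, "diagonal")
    if reference == "mask":
        lap_ref = np.full(index.size, lap[mask].mean())
        int_ref = np.full(index.size, image.pixels[mask].mean())
    else:
        lap_ref = ndimage.mean(lap, labels, index)
        int_ref = ndimage.mean(image.pixels, labels, index)
    ref_lap_img = np.zeros_like(lap)
    ref_int_img = np.zeros_like(lap)
    ref_lap_img[mask] = lap_ref[labels[mask] - 1]
    ref_int_img[mask] = int_ref[labels[mask] - 1]
    features = pd.DataFrame(
        {
            "pixel_intensity": ndimage.mean(image.pixels, labels, index),
            "energy_laplacian": ndimage.mean(lap**2, labels, index),
            "modified_laplacian": ndimage.mean(modified, labels, index),
            "diagonal_laplacian": ndimage.mean(diagonal, labels, index),
            "variance_laplacian": ndimage.mean((lap - ref_lap_img) ** 2, labels, index),
            "gray_level_variance": ndimage.mean((image.pixels - ref_int_img) ** 2, labels, index),
        },
        index=pd.Index(index, name="superpixel"),
    )
    return TextureTable(
        marker=image.marker_name,
        features=features,
        normalized=_minmax_columns(features),
    )
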