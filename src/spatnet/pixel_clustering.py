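"""Pixel-level phenotype clustering of multichannel cells.

Every cell-mask pixel becomes a feature vector of its per-marker intensities
(min-max scaled per marker), and K-Means partitions those vectors into
pixel phenotypes.  The number of clusters is either fixed (the published
analysis used k = 10) or chosen by the elbow method, formalized here as the
k maximizing the second-order forward difference of the inertia curve.
K-Means itself is scikit-learn's Lloyd implementation with seed-derived
k-means++ initializations; the best of several restarts is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .exceptions import DegenerateInputError, DimensionError, ValidationError
from .model import BinaryMask, CellRecord, ChannelImage


@dataclass(frozen=True)
class PixelMatrix:
    """Cell-mask pixels x markers feature matrix, min-max scaled per column."""

    values: np.ndarray  # (n_pixels, n_markers), each column in [0, 1]
    coords: np.ndarray  # (n_pixels, 2) int (row, col) inside the cell mask
    marker_order: tuple[str, ...]
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        coords = np.asarray(self.coords, dtype=np.intp)
        if values.ndim != 2 or coords.ndim != 2 or coords.shape[1] != 2:
            raise DimensionError("values must be (n, p) and coords (n, 2)")
        if values.shape[0] != coords.shape[0]:
            raise DimensionError("values and coords disagree on pixel count")
        if values.shape[1] != len(self.marker_order):
            raise DimensionError("column count must match marker_order")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "marker_order", tuple(self.marker_order))

    @property
    def n_pixels(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class ClusterResult:
    """K-Means output painted back into image space."""

    k: int
    labels: np.ndarray  # (n_pixels,) in 0..k-1
    centroids: np.ndarray  # (k, n_markers)
    label_image: np.ndarray  # image-shaped; 0 outside cell, 1..k inside
    profile: pd.DataFrame  # k x markers mean-intensity matrix
    inertia: float

    def __post_init__(self) -> None:
        if self.inertia < -1e-9:
            raise ValidationError(f"inertia must be >= 0, got {self.inertia}")
        labels = np.asarray(self.labels)
        if labels.size and (labels.min() < 0 or labels.max() > self.k - 1):
            raise ValidationError("labels out of 0..k-1")


def build_pixel_matrix(cell: CellRecord, markers: Sequence[str]) -> PixelMatrix:
    """Stack the cell's mask pixels into a per-marker feature matrix.

    Rows enumerate cell-mask pixels in row-major order; each column is
    min-max scaled over those pixels, with constant columns mapping to all
    zeros so a blank channel cannot derail clustering.
    """
    unknown = [m for m in markers if m not in cell.channels]
    if unknown:
        raise ValidationError(f"cell '{cell.cell_id}': unknown markers {unknown}")
    if not markers:
        raise ValidationError("markers must not be empty")
    coords = np.argwhere(cell.cell_mask.pixels)  # row-major order
    columns = []
    for marker in markers:
        col = cell.channels[marker].pixels[cell.cell_mask.pixels]
        vmin, vmax = col.min(), col.max()
        columns.append(np.zeros_like(col) if vmax == vmin else (col - vmin) / (vmax - vmin))
    return PixelMatrix(
        values=np.column_stack(columns),
        coords=coords,
        marker_order=tuple(markers),
        image_shape=cell.shape,
    )


def _as_array(matrix: Union[PixelMatrix, np.ndarray]) -> np.ndarray:
    if isinstance(matrix, PixelMatrix):
        return matrix.values
    arr = np.asarray(matrix, dtype=np.float64)
    if arr.ndim != 2:
        raise DimensionError(f"expected a 2D matrix, got shape {arr.shape}")
    return arr


def _fit_kmeans(data: np.ndarray, k: int, seed: int, n_init: int) -> KMeans:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points at large k
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed % (2**31), init="k-means++")
        km.fit(data)
    return km


def select_k_elbow(
    matrix: Union[PixelMatrix, np.ndarray],
    k_range: Sequence[int],
    seed: int,
    n_init: int = 3,
) -> tuple[int, pd.DataFrame]:
    """Choose k by the elbow criterion; return (k, per-k inertia table).

    K-Means runs at every k in ``k_range`` with the shared seed.  Each k also
    gets one warm-started run seeded from the previous k's centroids plus the
    point farthest from them, which guarantees the inertia curve is
    non-increasing in k.  The elbow is the interior k maximizing the
    second-order forward difference ``I(k-1) - 2 I(k) + I(k+1)`` of the
    inertia curve (ties break toward the smallest k); the full table is
    returned for audit.
    """
    data = _as_array(matrix)
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ValidationError(f"k_range needs >= 3 values for an elbow, got {ks}")
    if len(set(ks)) != len(ks):
        raise ValidationError(f"k_range contains duplicates: {ks}")
    if ks[0] < 1:
        raise ValidationError(f"all k must be >= 1, got {ks[0]}")
    if ks[-1] > data.shape[0]:
        raise ValidationError(f"k={ks[-1]} exceeds pixel count {data.shape[0]}")
    inertias = []
    prev_centers = None
    for k in ks:
        km = _fit_kmeans(data, k, seed, n_init)
        best_inertia, best_centers = float(km.inertia_), km.cluster_centers_
        if prev_centers is not None:
            # augment the previous solution with the worst-fit point: Lloyd
            # from this start can only improve on the previous inertia
            d2 = ((data[:, None, :] - prev_centers[None, :, :]) ** 2).sum(-1).min(1) \
                if data.shape[0] * prev_centers.shape[0] <= 2_000_000 else None
            if d2 is None:
                from scipy.spatial import cKDTree

                d2 = cKDTree(prev_centers).query(data)[0] ** 2
            extra = np.vstack([prev_centers] + [data[np.argmax(d2)][None, :]] * (k - len(prev_centers)))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                warm = KMeans(n_clusters=k, n_init=1, init=extra).fit(data)
            if float(warm.inertia_) < best_inertia:
                best_inertia, best_centers = float(warm.inertia_), warm.cluster_centers_
        inertias.append(best_inertia)
        prev_centers = best_centers
    inertia = np.asarray(inertias)
    second_diff = inertia[:-2] - 2 * inertia[1:-1] + inertia[2:]
    selected = ks[1 + int(np.argmax(second_diff))]
    table = pd.DataFrame({"k": ks, "inertia": inertias})
    return selected, table


def cluster_pixels(
    matrix: PixelMatrix, k: int, seed: int, n_init: int = 10
) -> ClusterResult:
    """K-Means partition of the pixel matrix into ``k`` pixel phenotypes.

    Runs ``n_init`` seed-derived k-means++ restarts and keeps the lowest
    inertia.  The label image paints cluster ids 1..k inside the cell and 0
    outside; the profile holds each cluster's mean scaled intensity per
    marker.
    """
    if not 1 <= k <= matrix.n_pixels:
        raise ValidationError(f"k={k} out of 1..{matrix.n_pixels}")
    km = _fit_kmeans(matrix.values, k, seed, n_init)
    labels = km.labels_.astype(np.intp)
    label_image = np.zeros(matrix.image_shape, dtype=np.int32)
    label_image[matrix.coords[:, 0], matrix.coords[:, 1]] = labels + 1
    profile = pd.DataFrame(
        [matrix.values[labels == c].mean(axis=0) if np.any(labels == c) else np.full(len(matrix.marker_order), np.nan)
         for c in range(k)],
        columns=list(matrix.marker_order),
        index=pd.RangeIndex(k, name="cluster"),
    )
    return ClusterResult(
        k=k,
        labels=labels,
        centroids=km.cluster_centers_.copy(),
        label_image=label_image,
        profile=profile,
        inertia=float(km.inertia_),
    )


def organelle_product_image(
    image_a: ChannelImage, image_b: ChannelImage, mask: BinaryMask
) -> ChannelImage:
    """Pixel-wise product of two min-max scaled channels, highlighting overlap.

    Each channel is min-max scaled over the mask before multiplying, so the
    output lies in [0, 1], peaking where both markers are bright together.
    """
    if image_a.shape != image_b.shape or image_a.shape != mask.shape:
        raise DimensionError(
            f"shapes differ: {image_a.shape}, {image_b.shape}, mask {mask.shape}"
        )
    if mask.area == 0:
        raise ValidationError("mask is empty")
    out = np.zeros(image_a.shape, dtype=np.float64)
    scaled = []
    for img in (image_a, image_b):
        vals = img.pixels[mask.pixels]
        vmin, vmax = vals.min(), vals.max()
        if vmax == vmin:
            raise DegenerateInputError(
                f"channel '{img.marker_name}' is constant within the mask"
            )
        scaled.append((vals - vmin) / (vmax - vmin))
    out[mask.pixels] = scaled[0] * scaled[1]
    return ChannelImage(
        out,
        marker_name=f"{image_a.marker_name}*{image_b.marker_name}",
        pixel_size_um=image_a.pixel_size_um,
    )
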