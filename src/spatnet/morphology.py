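"""Per-marker shape profiling and hierarchically ordered heatmap tables.

Each marker's Otsu foreground within a cell is measured as a single object
(the union of all its connected components): pixel area and the major/minor
axis lengths of the ellipse with identical normalized second central moments
(``4 * sqrt(eigenvalue)``).  Feature tables are z-scored per column and
ordered by average-linkage hierarchical clustering on correlation distance,
which is the layout used for the published morphology heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .exceptions import DegenerateInputError, ValidationError
from .model import BinaryMask


@dataclass(frozen=True)
class ShapeRow:
    """Area and equal-moment-ellipse axes of one marker's foreground."""

    cell_id: str
    group: str
    marker: str
    area_px: int
    area_um2: float
    major_axis_px: float
    minor_axis_px: float

    def __post_init__(self) -> None:
        if not (self.major_axis_px >= self.minor_axis_px >= 0):
            raise ValidationError(
                f"need major >= minor >= 0, got ({self.major_axis_px}, {self.minor_axis_px})"
            )
        if self.area_px < 0:
            raise ValidationError(f"area_px must be >= 0, got {self.area_px}")


@dataclass(frozen=True)
class HierarchicalOrder:
    """Leaf orders and merge trees from average-linkage clustering."""

    row_order: np.ndarray
    col_order: np.ndarray
    row_linkage: np.ndarray  # scipy linkage matrix (merge tree)
    col_linkage: np.ndarray


def shape_features(
    foreground: BinaryMask,
    pixel_size_um: float,
    cell_id: str = "",
    group: str = "",
    marker: str = "",
) -> ShapeRow:
    """Area and major/minor axes of the foreground, treated as one object.

    The axes are those of the ellipse whose normalized second central
    moments match the region's: ``4 * sqrt(lambda)`` for the two eigenvalues
    of the coordinate covariance (the convention of common morphometry
    suites).  All foreground pixels contribute, whether or not they are
    connected, since a marker is summarized by one triple per cell.
    """
    if foreground.area == 0:
        raise ValidationError("foreground is empty")
    if pixel_size_um <= 0:
        raise ValidationError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    coords = np.argwhere(foreground.pixels).astype(np.float64)
    area = coords.shape[0]
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / area  # second central moments / area
    eigvals = np.linalg.eigvalsh(cov)  # ascending
    minor = 4.0 * np.sqrt(max(eigvals[0], 0.0))
    major = 4.0 * np.sqrt(max(eigvals[1], 0.0))
    return ShapeRow(
        cell_id=cell_id,
        group=group,
        marker=marker,
        area_px=int(area),
        area_um2=area * pixel_size_um**2,
        major_axis_px=float(major),
        minor_axis_px=float(minor),
    )


def zscore_normalize(table: Union[pd.DataFrame, np.ndarray]) -> Union[pd.DataFrame, np.ndarray]:
    """Per-column z-score with sample standard deviation (ddof=1).

    Each column maps to mean 0 and sd 1; constant columns map to all zeros.
    Requires at least 2 rows.
    """
    is_frame = isinstance(table, pd.DataFrame)
    values = table.to_numpy(dtype=np.float64) if is_frame else np.asarray(table, dtype=np.float64)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValidationError(f"need a 2D table with >= 2 rows, got shape {values.shape}")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    out = np.zeros_like(values)
    nonconst = sd > 0
    out[:, nonconst] = (values[:, nonconst] - mean[nonconst]) / sd[nonconst]
    if is_frame:
        return pd.DataFrame(out, index=table.index, columns=table.columns)
    return out


def _correlation_linkage(values: np.ndarray, fallback_constant: bool) -> np.ndarray:
    sd = values.std(axis=1)
    if np.any(sd == 0):
        if not fallback_constant:
            raise DegenerateInputError(
                "constant row: correlation distance undefined "
                "(pass fallback_constant=True to assign distance 1)"
            )
        dist = pdist(values, metric="correlation")
        dist = np.nan_to_num(dist, nan=1.0)
        return linkage(dist, method="average")
    return linkage(values, method="average", metric="correlation")


def hierarchical_order(
    matrix: Union[pd.DataFrame, np.ndarray],
    fallback_constant: bool = False,
) -> HierarchicalOrder:
    """Average-linkage ordering of rows and columns on correlation distance.

    Distance is ``1 - Pearson(x, y)``.  Returns leaf orders (permutations of
    the row/column index sets) plus both merge trees.  A constant row or
    column makes the correlation undefined; with ``fallback_constant`` it is
    placed at distance 1 from everything instead of raising.
    """
    values = (
        matrix.to_numpy(dtype=np.float64)
        if isinstance(matrix, pd.DataFrame)
        else np.asarray(matrix, dtype=np.float64)
    )
    if values.ndim != 2 or values.shape[0] < 2 or values.shape[1] < 2:
        raise ValidationError(f"need a 2D matrix with >= 2 rows and columns, got {values.shape}")
    row_linkage = _correlation_linkage(values, fallback_constant)
    col_linkage = _correlation_linkage(values.T, fallback_constant)
    return HierarchicalOrder(
        row_order=np.asarray(leaves_list(row_linkage), dtype=np.intp),
        col_order=np.asarray(leaves_list(col_linkage), dtype=np.intp),
        row_linkage=row_linkage,
        col_linkage=col_linkage,
    )
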