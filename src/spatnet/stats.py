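"""Group comparison and radial-distribution hypothesis testing.

Two procedures:

* Mann-Whitney U comparison of a per-cell feature between groups (e.g. BM vs
  UC Pearson correlations of a marker pair), with the conventional
  significance tiers ``ns / * / ** / *** / ****``;
* the radial Kolmogorov-Smirnov procedure: each marker's foreground pixels
  are reduced to their Euclidean distances from the cell-mask center of
  mass, turning the 2D spatial pattern into a 1D distribution, and two
  markers of the same cell are compared by a two-sample KS test.  The null
  hypothesis is that similar proteins express similar spatial distributions
  within the cell.

No multiple-testing correction is applied; tables carry raw p values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .exceptions import DegenerateInputError, ValidationError
from .model import BinaryMask

#: maximum n_a * n_b for which the exact Mann-Whitney null is enumerated
EXACT_MWU_LIMIT = 400

TIERS = (
    (1e-4, "****"),
    (1e-3, "***"),
    (1e-2, "**"),
    (5e-2, "*"),
)


def significance_tier(p: float) -> str:
    """Map a p value to its star tier (ns for p >= 0.05, **** for p <= 1e-4)."""
    if not (0.0 <= p <= 1.0):
        raise ValidationError(f"p value out of [0, 1]: {p}")
    if p <= 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 5e-2:
        return "*"
    return "ns"


@dataclass(frozen=True)
class GroupComparisonRow:
    """One Mann-Whitney comparison of a feature between two groups."""

    feature: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    tier: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.u_statistic <= self.n_a * self.n_b + 1e-9):
            raise ValidationError(
                f"U={self.u_statistic} out of [0, {self.n_a * self.n_b}]"
            )
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p value out of [0, 1]: {self.p_value}")
        if self.tier != significance_tier(self.p_value):
            raise ValidationError(f"tier {self.tier!r} inconsistent with p={self.p_value}")


@dataclass(frozen=True)
class RadialSample:
    """Distances from a marker's foreground pixels to the cell center of mass."""

    cell_id: str
    marker: str
    distances: np.ndarray
    weights: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        distances = np.asarray(self.distances, dtype=np.float64)
        if distances.ndim != 1 or distances.size == 0:
            raise ValidationError("distances must be a nonempty 1D sample")
        if distances.min() < 0:
            raise ValidationError("distances must be >= 0")
        object.__setattr__(self, "distances", distances)
        if self.weights is not None:
            weights = np.asarray(self.weights, dtype=np.float64)
            if weights.shape != distances.shape or weights.min() < 0 or weights.sum() == 0:
                raise ValidationError("weights must be non-negative, same length, not all zero")
            object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return int(self.distances.size)


class KsResult(NamedTuple):
    statistic: float
    p_value: float
    tier: str


def mann_whitney_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    feature: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparisonRow:
    """Two-sided Mann-Whitney U test with midrank tie handling.

    Uses the exact null distribution when ``n_a * n_b <= 400`` and the data
    are tie-free, otherwise the normal approximation with continuity and tie
    correction.  The reported U statistic is that of ``values_a``.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= EXACT_MWU_LIMIT and not has_ties) else "asymptotic"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # all-tied data -> zero variance warning
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    p = float(res.pvalue)
    if np.isnan(p):  # every value tied across both groups: no evidence at all
        p = 1.0
    return GroupComparisonRow(
        feature=feature,
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=float(res.statistic),
        p_value=p,
        tier=significance_tier(p),
    )


def center_of_mass(cell_mask: BinaryMask) -> tuple[float, float]:
    """Unweighted mean (row, col) of the cell-mask foreground coordinates."""
    if cell_mask.area == 0:
        raise ValidationError("cell_mask is empty")
    coords = np.argwhere(cell_mask.pixels)
    return float(coords[:, 0].mean()), float(coords[:, 1].mean())


def radial_distribution(
    foreground: BinaryMask,
    cell_mask: BinaryMask,
    cell_id: str,
    marker: str,
    intensities: Optional[np.ndarray] = None,
) -> RadialSample:
    """1D radial sample of a marker's foreground pixels (distances in pixels).

    The reference point is the unweighted center of mass of the cell mask.
    Passing ``intensities`` attaches per-pixel intensity weights for the
    intensity-weighted variant of the KS procedure; the default treats each
    foreground pixel equally.
    """
    if foreground.shape != cell_mask.shape:
        raise ValidationError(
            f"foreground {foreground.shape} vs cell_mask {cell_mask.shape}"
        )
    if foreground.area == 0:
        raise DegenerateInputError(f"marker '{marker}': foreground is empty")
    com_r, com_c = center_of_mass(cell_mask)
    coords = np.argwhere(foreground.pixels)
    distances = np.hypot(coords[:, 0] - com_r, coords[:, 1] - com_c)
    weights = None
    if intensities is not None:
        intensities = np.asarray(intensities, dtype=np.float64)
        if intensities.shape != foreground.shape:
            raise ValidationError("intensities must match the mask shape")
        weights = intensities[foreground.pixels]
    return RadialSample(cell_id=cell_id, marker=marker, distances=distances, weights=weights)


def _weighted_ks(sample_a: RadialSample, sample_b: RadialSample) -> tuple[float, float]:
    """Weighted two-sample KS with Kish effective sample sizes."""
    def wecdf(sample: RadialSample, grid: np.ndarray) -> np.ndarray:
        order = np.argsort(sample.distances, kind="stable")
        x = sample.distances[order]
        w = sample.weights[order] / sample.weights.sum()
        cum = np.cumsum(w)
        return cum[np.clip(np.searchsorted(x, grid, side="right") - 1, 0, None)] * (
            np.searchsorted(x, grid, side="right") > 0
        )

    grid = np.unique(np.concatenate([sample_a.distances, sample_b.distances]))
    d = float(np.max(np.abs(wecdf(sample_a, grid) - wecdf(sample_b, grid))))
    def kish(w: np.ndarray) -> float:
        return float(w.sum() ** 2 / (w * w).sum())
    n_eff = kish(sample_a.weights) * kish(sample_b.weights) / (
        kish(sample_a.weights) + kish(sample_b.weights)
    )
    p = float(sps.kstwobign.sf(max(np.sqrt(n_eff) * d, 0.0)))
    return d, min(1.0, max(0.0, p))


def ks_radial_test(sample_a: RadialSample, sample_b: RadialSample) -> KsResult:
    """Two-sample Kolmogorov-Smirnov test of two radial samples of one cell.

    ``D = sup |ECDF_a - ECDF_b|`` with the asymptotic two-sided p value.
    Both samples must come from the same cell.  If both samples carry
    intensity weights, weighted ECDFs and Kish effective sample sizes are
    used instead.
    """
    if sample_a.cell_id != sample_b.cell_id:
        raise ValidationError(
            f"samples from different cells: '{sample_a.cell_id}' vs '{sample_b.cell_id}'"
        )
    if sample_a.weights is not None and sample_b.weights is not None:
        d, p = _weighted_ks(sample_a, sample_b)
    else:
        res = sps.ks_2samp(sample_a.distances, sample_b.distances, method="asymp")
        d, p = float(res.statistic), float(res.pvalue)
    p = min(1.0, max(0.0, p))
    return KsResult(statistic=d, p_value=p, tier=significance_tier(p))
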