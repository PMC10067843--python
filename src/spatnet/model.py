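"""Core domain types for single-cell multiplexed-immunofluorescence analysis.

The unit of analysis is one segmented cell (:class:`CellRecord`): a set of
named 2D marker channels (:class:`ChannelImage`) sharing one shape, a binary
cell mask, an optional nucleus mask, and a group label (e.g. ``"BM"`` /
``"UC"`` for bone-marrow vs umbilical-cord mesenchymal stem cells).

Intensities are stored as float64 in the original camera units: integer TIFF
inputs are promoted without rescaling, and normalization only happens inside
operations that explicitly call for it.

Coordinate convention throughout the package: row-major, 0-based ``(row,
col)`` with row 0 at the top of the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .exceptions import DimensionError, ValidationError

#: Default physical pixel pitch of the acquisition (60x oil objective).
DEFAULT_PIXEL_SIZE_UM = 0.1083


def pixels_to_um(n_pixels: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Convert a length in pixels to micrometres.

    Example: a histogram bin of 12.5 pixels at 0.1083 um/pixel spans
    ``pixels_to_um(12.5, 0.1083) == 1.35375`` um (1.354 um to printed
    precision).
    """
    if pixel_size_um <= 0:
        raise ValidationError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return float(n_pixels) * float(pixel_size_um)


def um_to_pixels(length_um: float, pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> float:
    """Convert a length in micrometres to pixels."""
    if pixel_size_um <= 0:
        raise ValidationError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    return float(length_um) / float(pixel_size_um)


@dataclass(frozen=True)
class ChannelImage:
    """One marker channel of one cell: a 2D grid of non-negative intensities."""

    pixels: np.ndarray
    marker_name: str
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise DimensionError(
                f"channel '{self.marker_name}' must be a 2D grid, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"channel '{self.marker_name}' contains non-finite values")
        if arr.min() < 0:
            raise ValidationError(f"channel '{self.marker_name}' contains negative intensities")
        if not self.pixel_size_um > 0:
            raise ValidationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray, marker_name: Optional[str] = None) -> "ChannelImage":
        """Return a copy carrying new pixel values but the same metadata."""
        return ChannelImage(
            pixels=pixels,
            marker_name=self.marker_name if marker_name is None else marker_name,
            pixel_size_um=self.pixel_size_um,
        )


@dataclass(frozen=True)
class BinaryMask:
    """A 2D boolean mask; shape must match the image(s) it accompanies."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise DimensionError(f"mask must be 2D, got shape {arr.shape}")
        object.__setattr__(self, "pixels", arr.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def area(self) -> int:
        """Foreground pixel count."""
        return int(np.count_nonzero(self.pixels))

    def __and__(self, other: "BinaryMask") -> "BinaryMask":
        if self.shape != other.shape:
            raise DimensionError(f"mask shapes differ: {self.shape} vs {other.shape}")
        return BinaryMask(self.pixels & other.pixels)


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell with all of its marker channels and masks."""

    cell_id: str
    group: str
    channels: Mapping[str, ChannelImage]
    cell_mask: BinaryMask
    nucleus_mask: Optional[BinaryMask] = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValidationError(f"cell '{self.cell_id}' has no channels")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        ref_shape = next(iter(shapes.values()))
        for name, shp in shapes.items():
            if shp != ref_shape:
                raise DimensionError(
                    f"cell '{self.cell_id}': channel '{name}' has shape {shp}, "
                    f"expected {ref_shape}"
                )
        if self.cell_mask.shape != ref_shape:
            raise DimensionError(
                f"cell '{self.cell_id}': cell_mask shape {self.cell_mask.shape} "
                f"does not match channels {ref_shape}"
            )
        if self.cell_mask.area < 1:
            raise ValidationError(f"cell '{self.cell_id}': cell_mask is empty")
        if self.nucleus_mask is not None:
            if self.nucleus_mask.shape != ref_shape:
                raise DimensionError(
                    f"cell '{self.cell_id}': nucleus_mask shape "
                    f"{self.nucleus_mask.shape} does not match channels {ref_shape}"
                )
            if np.any(self.nucleus_mask.pixels & ~self.cell_mask.pixels):
                raise ValidationError(
                    f"cell '{self.cell_id}': nucleus_mask is not a subset of cell_mask"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_mask.shape

    @property
    def marker_names(self) -> list[str]:
        return list(self.channels)

    @property
    def pixel_size_um(self) -> float:
        return next(iter(self.channels.values())).pixel_size_um


@dataclass(frozen=True)
class PairStatRow:
    """Per-cell colocalization of one marker pair."""

    cell_id: str
    marker_a: str
    marker_b: str
    pearson_r: float
    overlap_fraction: float

    _TOL = 1e-9

    def __post_init__(self) -> None:
        if self.marker_a == self.marker_b:
            raise ValidationError(f"marker pair must be distinct, got '{self.marker_a}' twice")
        if not (-1.0 - self._TOL <= self.pearson_r <= 1.0 + self._TOL):
            raise ValidationError(f"pearson_r out of [-1, 1]: {self.pearson_r}")
        if not (0.0 <= self.overlap_fraction <= 0.5 + self._TOL):
            raise ValidationError(f"overlap_fraction out of [0, 0.5]: {self.overlap_fraction}")


@dataclass(frozen=True)
class MarkerSummaryRow:
    """Per-cell area and mean intensity of one marker."""

    cell_id: str
    marker: str
    area_px: int
    area_um2: float
    mean_intensity: float

    def __post_init__(self) -> None:
        if self.area_px < 0:
            raise ValidationError(f"area_px must be >= 0, got {self.area_px}")
        if self.mean_intensity < 0:
            raise ValidationError(f"mean_intensity must be >= 0, got {self.mean_intensity}")


@dataclass
class AnalysisConfig:
    """Run configuration; maps 1:1 onto the YAML config file.

    Defaults follow the published pipeline settings where they exist: the
    20th / 99.9th percentile intensity window, 50,000-pixel scatter samples,
    250 superpixels per cell, and 10 pixel-phenotype clusters.
    """

    low_percentile: float = 20.0
    high_percentile: float = 99.9
    scatter_sample_n: int = 50_000
    n_superpixels: int = 250
    kmeans_k: int = 10
    k_range: Sequence[int] = field(default_factory=lambda: list(range(2, 16)))
    rolling_ball_radius_px: float = 50.0
    rng_seed: int = 0
    significance_alpha: float = 0.05
    # secondary knobs (documented defaults; rarely changed)
    overlap_denominator: str = "sum"  # "sum" -> |A|+|B|; "union" -> |A u B| (Jaccard)
    slic_compactness: float = 0.1
    elbow_n_init: int = 3
    kmeans_n_init: int = 10
    kde_max_train: int = 2000

    def __post_init__(self) -> None:
        if not (0 <= self.low_percentile < self.high_percentile <= 100):
            raise ValidationError(
                f"need 0 <= low < high <= 100, got "
                f"({self.low_percentile}, {self.high_percentile})"
            )
        if self.scatter_sample_n < 1:
            raise ValidationError("scatter_sample_n must be >= 1")
        if self.n_superpixels < 1:
            raise ValidationError("n_superpixels must be >= 1")
        if self.kmeans_k < 1:
            raise ValidationError("kmeans_k must be >= 1")
        self.k_range = [int(k) for k in self.k_range]
        if any(k < 1 for k in self.k_range):
            raise ValidationError("all k in k_range must be >= 1")
        if self.rolling_ball_radius_px < 1:
            raise ValidationError("rolling_ball_radius_px must be >= 1")
        if self.overlap_denominator not in ("sum", "union"):
            raise ValidationError(
                f"overlap_denominator must be 'sum' or 'union', got {self.overlap_denominator!r}"
            )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        data["k_range"] = list(self.k_range)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
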