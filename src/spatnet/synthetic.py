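"""Synthetic single-cell multichannel image generator.

Real input to this pipeline is a segmented mesenchymal stem cell imaged by
iterative immunofluorescence: per-marker 16-bit grayscale channels plus a
cell mask drawn from a cytoskeletal stain. This module emulates that data
with known ground truth so every downstream stage can be tested:

* the cell is an ellipse, the nucleus a smaller ellipse inside it;
* each marker is a sum of Gaussian intensity blobs whose centers are placed
  inside the cell (or nucleus) with a configurable radial bias;
* pairwise colocalization is injected by copying a configurable fraction of
  one marker's blob centers into another's (``overlap_targets``);
* realism comes from a smooth additive background restricted to the cell
  interior, Poisson (shot) noise and additive Gaussian (read) noise.

Radial bias is implemented by drawing each blob's radius as a Beta-distributed
fraction of the ellipse's boundary radius along a uniform angle.  ``bias = 0``
maps to Beta(2, 1), the area-uniform law on an ellipse; positive bias
increases the first shape parameter (periphery-heavy), negative bias the
second (center-heavy).  The mapping is monotone in the mean radius, which is
all the radial statistics need.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .exceptions import ValidationError
from .model import DEFAULT_PIXEL_SIZE_UM, BinaryMask, CellRecord, ChannelImage


@dataclass(frozen=True)
class Ellipse:
    """An ellipse in image coordinates: center (row, col), semi-axes, rotation.

    ``rotation_deg`` rotates the first semi-axis from the row axis toward the
    column axis.
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    rotation_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.semi_axes[0] <= 0 or self.semi_axes[1] <= 0:
            raise ValidationError(f"ellipse semi-axes must be > 0, got {self.semi_axes}")

    def _frame(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map image coordinates into the ellipse's own (u, v) frame."""
        theta = math.radians(self.rotation_deg)
        dr = rows - self.center[0]
        dc = cols - self.center[1]
        u = dr * math.cos(theta) + dc * math.sin(theta)
        v = -dr * math.sin(theta) + dc * math.cos(theta)
        return u, v

    def contains(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        u, v = self._frame(np.asarray(rows, float), np.asarray(cols, float))
        a, b = self.semi_axes
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def rasterize(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.contains(rr, cc)

    def boundary_points(self, n: int = 256) -> np.ndarray:
        """(n, 2) array of (row, col) boundary samples."""
        theta = math.radians(self.rotation_deg)
        t = np.linspace(0, 2 * math.pi, n, endpoint=False)
        a, b = self.semi_axes
        u = a * np.cos(t)
        v = b * np.sin(t)
        rows = self.center[0] + u * math.cos(theta) - v * math.sin(theta)
        cols = self.center[1] + u * math.sin(theta) + v * math.cos(theta)
        return np.column_stack([rows, cols])

    def fits_inside(self, shape: tuple[int, int]) -> bool:
        pts = self.boundary_points()
        return bool(
            (pts[:, 0] >= 0).all()
            and (pts[:, 1] >= 0).all()
            and (pts[:, 0] <= shape[0] - 1).all()
            and (pts[:, 1] <= shape[1] - 1).all()
        )

    def contains_ellipse(self, other: "Ellipse") -> bool:
        pts = other.boundary_points()
        return bool(self.contains(pts[:, 0], pts[:, 1]).all())


@dataclass(frozen=True)
class MarkerSpec:
    """Ground-truth description of one marker channel."""

    marker_name: str
    n_blobs: int
    blob_sigma_px: float
    amplitude: float
    radial_bias: float = 0.0
    nuclear: bool = False

    def __post_init__(self) -> None:
        if self.n_blobs < 0:
            raise ValidationError(f"{self.marker_name}: n_blobs must be >= 0")
        if self.blob_sigma_px <= 0:
            raise ValidationError(f"{self.marker_name}: blob_sigma_px must be > 0")
        if self.amplitude <= 0:
            raise ValidationError(f"{self.marker_name}: amplitude must be > 0")
        if not (-1.0 <= self.radial_bias <= 1.0):
            raise ValidationError(f"{self.marker_name}: radial_bias must be in [-1, 1]")


@dataclass(frozen=True)
class SyntheticCellSpec:
    """Full recipe for one synthetic cell."""

    image_shape: tuple[int, int]
    cell_ellipse: Ellipse
    nucleus_ellipse: Ellipse
    markers: Sequence[MarkerSpec]
    overlap_targets: Mapping[tuple[str, str], float] = field(default_factory=dict)
    background_level: float = 0.0
    gaussian_noise_sd: float = 0.0
    poisson_noise: bool = False
    rng_seed: int = 0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    #: optional per-marker integer (row, col) translation, applied last;
    #: exists only to exercise translational registration.
    channel_shifts: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.background_level < 0:
            raise ValidationError("background_level must be >= 0")
        if self.gaussian_noise_sd < 0:
            raise ValidationError("gaussian_noise_sd must be >= 0")
        names = [m.marker_name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate marker names: {names}")
        for (a, b), f in self.overlap_targets.items():
            if not (0.0 <= f <= 1.0):
                raise ValidationError(f"overlap_targets[({a}, {b})] must be in [0, 1], got {f}")
            if a not in names or b not in names:
                raise ValidationError(f"overlap_targets names unknown marker: ({a}, {b})")
        if not self.cell_ellipse.fits_inside(self.image_shape):
            raise ValidationError("cell_ellipse does not fit inside image_shape")
        if not self.cell_ellipse.contains_ellipse(self.nucleus_ellipse):
            raise ValidationError("nucleus_ellipse is not contained in cell_ellipse")


def _bias_beta_params(bias: float) -> tuple[float, float]:
    """Map radial bias in [-1, 1] to Beta shape parameters for the radius."""
    return 2.0 + 6.0 * max(bias, 0.0), 1.0 + 6.0 * max(-bias, 0.0)


def _sample_blob_centers(
    rng: np.random.Generator, region: Ellipse, n: int, bias: float
) -> np.ndarray:
    """Sample (n, 2) blob centers inside ``region`` with the given radial bias."""
    if n == 0:
        return np.empty((0, 2))
    a_p, b_p = _bias_beta_params(bias)
    t = rng.uniform(0.0, 2.0 * math.pi, size=n)
    r_frac = rng.beta(a_p, b_p, size=n)
    theta = math.radians(region.rotation_deg)
    a, b = region.semi_axes
    u = r_frac * a * np.cos(t)
    v = r_frac * b * np.sin(t)
    rows = region.center[0] + u * math.cos(theta) - v * math.sin(theta)
    cols = region.center[1] + u * math.sin(theta) + v * math.cos(theta)
    return np.column_stack([rows, cols])


def _render_blobs(
    shape: tuple[int, int], centers: np.ndarray, sigma: float, amplitude: float
) -> np.ndarray:
    """Sum of isotropic Gaussian blobs, each rendered on a +-4 sigma window."""
    img = np.zeros(shape, dtype=np.float64)
    half = max(1, int(math.ceil(4.0 * sigma)))
    for cr, cc in centers:
        r0 = max(0, int(math.floor(cr)) - half)
        r1 = min(shape[0], int(math.ceil(cr)) + half + 1)
        c0 = max(0, int(math.floor(cc)) - half)
        c1 = min(shape[1], int(math.ceil(cc)) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rr = np.arange(r0, r1, dtype=np.float64)[:, None]
        ccs = np.arange(c0, c1, dtype=np.float64)[None, :]
        img[r0:r1, c0:c1] += amplitude * np.exp(
            -((rr - cr) ** 2 + (ccs - cc) ** 2) / (2.0 * sigma**2)
        )
    return img


def generate_cell(spec: SyntheticCellSpec, cell_id: str = "cell", group: str = "NA") -> CellRecord:
    """Render one synthetic cell; fully reproducible from ``spec.rng_seed``."""
    rng = np.random.default_rng(spec.rng_seed)
    cell_mask = spec.cell_ellipse.rasterize(spec.image_shape)
    nucleus_mask = spec.nucleus_ellipse.rasterize(spec.image_shape) & cell_mask

    # sample every marker's blob centers first so the noise draws below never
    # perturb blob placement across noise configurations
    centers: dict[str, np.ndarray] = {}
    for marker in spec.markers:
        region = spec.nucleus_ellipse if marker.nuclear else spec.cell_ellipse
        centers[marker.marker_name] = _sample_blob_centers(
            rng, region, marker.n_blobs, marker.radial_bias
        )
    for (src, dst), frac in spec.overlap_targets.items():
        n_dst = len(centers[dst])
        n_copy = int(round(frac * n_dst))
        if n_copy == 0 or len(centers[src]) == 0:
            continue
        pool = centers[src]
        idx = rng.permutation(len(pool))
        take = np.resize(idx, n_copy)  # cycle if the source has fewer blobs
        copied = pool[take]
        centers[dst] = np.vstack([copied, centers[dst][n_copy:]])

    channels: dict[str, ChannelImage] = {}
    for marker in spec.markers:
        img = _render_blobs(
            spec.image_shape, centers[marker.marker_name], marker.blob_sigma_px, marker.amplitude
        )
        img += spec.background_level
        img *= cell_mask  # background is cell-restricted; nothing outside the cell
        if spec.poisson_noise:
            img = rng.poisson(img).astype(np.float64)
        noise = rng.normal(0.0, spec.gaussian_noise_sd, size=spec.image_shape)
        img = np.clip(img + noise * cell_mask, 0.0, None)
        shift = spec.channel_shifts.get(marker.marker_name)
        if shift is not None:
            img = np.roll(img, shift, axis=(0, 1))
        channels[marker.marker_name] = ChannelImage(
            img, marker_name=marker.marker_name, pixel_size_um=spec.pixel_size_um
        )

    mask = cell_mask
    if spec.channel_shifts:
        # a shifted channel may carry signal outside the nominal ellipse;
        # registration tests use the un-shifted mask on purpose
        pass
    return CellRecord(
        cell_id=cell_id,
        group=group,
        channels=channels,
        cell_mask=BinaryMask(mask),
        nucleus_mask=BinaryMask(nucleus_mask),
    )


def derive_seed(master_seed: int, *indices: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_population(
    n_per_group: Mapping[str, int],
    group_specs: Mapping[str, SyntheticCellSpec],
    seed: int,
    vary_geometry: bool = True,
) -> list[CellRecord]:
    """Generate a labeled population of cells from per-group spec templates.

    Per-cell seeds are derived deterministically from the master seed.  With
    ``vary_geometry`` each cell's ellipses are shrunk by a random factor in
    [0.85, 1] and re-rotated so the population has realistic size variation
    (shrink-only, so the geometry invariants of the template still hold).
    """
    if not n_per_group:
        raise ValidationError("n_per_group must not be empty")
    for group, count in n_per_group.items():
        if count < 1:
            raise ValidationError(f"group '{group}': count must be >= 1, got {count}")
        if group not in group_specs:
            raise ValidationError(f"group '{group}' has no spec template")
    cells: list[CellRecord] = []
    for g_idx, (group, count) in enumerate(sorted(n_per_group.items())):
        template = group_specs[group]
        for i in range(count):
            cell_seed = derive_seed(seed, g_idx, i)
            spec = replace(template, rng_seed=cell_seed)
            if vary_geometry:
                geo = np.random.default_rng(derive_seed(seed, g_idx, i, 7919))
                scale = geo.uniform(0.85, 1.0)
                rot = geo.uniform(0.0, 180.0)
                cell_e = template.cell_ellipse
                nuc_e = template.nucleus_ellipse
                offset = (
                    nuc_e.center[0] - cell_e.center[0],
                    nuc_e.center[1] - cell_e.center[1],
                )
                spec = replace(
                    spec,
                    cell_ellipse=Ellipse(
                        cell_e.center,
                        (cell_e.semi_axes[0] * scale, cell_e.semi_axes[1] * scale),
                        rot,
                    ),
                    nucleus_ellipse=Ellipse(
                        (cell_e.center[0] + offset[0] * scale, cell_e.center[1] + offset[1] * scale),
                        (nuc_e.semi_axes[0] * scale, nuc_e.semi_axes[1] * scale),
                        rot,
                    ),
                )
            cells.append(generate_cell(spec, cell_id=f"{group}_{i + 1:02d}", group=group))
    return cells


# --------------------------------------------------------------------------
# Default study emulation: a 5-marker panel on a 7 + 7 BM/UC population.
# --------------------------------------------------------------------------

def default_marker_panel(amplitude_scale: float = 1.0) -> list[MarkerSpec]:
    """Five-marker panel emulating the study's single-cell selection.

    DAPI and Nucleolin are nuclear; TOM20/HSP60 emulate punctate mitochondrial
    staining with a mild peripheral bias and strong mutual overlap; GOLPH4 is
    perinuclear (Golgi-like, center-biased); ATF6 is ER-like and spread.
    Amplitudes are on a 16-bit-camera scale.
    """
    s = float(amplitude_scale)
    return [
        MarkerSpec("DAPI", n_blobs=25, blob_sigma_px=5.0, amplitude=8000 * s, nuclear=True),
        MarkerSpec("Nucleolin", n_blobs=6, blob_sigma_px=3.0, amplitude=6000 * s, nuclear=True),
        MarkerSpec("TOM20", n_blobs=150, blob_sigma_px=2.0, amplitude=3000 * s, radial_bias=0.2),
        MarkerSpec("HSP60", n_blobs=150, blob_sigma_px=2.0, amplitude=3000 * s, radial_bias=0.2),
        MarkerSpec("GOLPH4", n_blobs=60, blob_sigma_px=2.5, amplitude=4000 * s, radial_bias=-0.5),
        MarkerSpec("ATF6", n_blobs=80, blob_sigma_px=2.5, amplitude=3500 * s, radial_bias=0.0),
    ]


DEFAULT_OVERLAP_TARGETS: dict[tuple[str, str], float] = {
    ("TOM20", "HSP60"): 0.7,
    ("GOLPH4", "ATF6"): 0.3,
}


def default_cell_spec(
    image_shape: tuple[int, int] = (256, 256),
    amplitude_scale: float = 1.0,
    rng_seed: int = 0,
) -> SyntheticCellSpec:
    """Template cell spec used for the emulated BM/UC populations."""
    h, w = image_shape
    center = (h / 2.0, w / 2.0)
    cell = Ellipse(center, (0.375 * h, 0.30 * w), rotation_deg=15.0)
    nucleus = Ellipse((center[0] - 0.03 * h, center[1] + 0.02 * w), (0.13 * h, 0.11 * w), 15.0)
    return SyntheticCellSpec(
        image_shape=image_shape,
        cell_ellipse=cell,
        nucleus_ellipse=nucleus,
        markers=default_marker_panel(amplitude_scale),
        overlap_targets=dict(DEFAULT_OVERLAP_TARGETS),
        background_level=20.0,
        gaussian_noise_sd=10.0,
        poisson_noise=True,
        rng_seed=rng_seed,
    )


def default_population_specs(
    image_shape: tuple[int, int] = (256, 256),
) -> dict[str, SyntheticCellSpec]:
    """BM/UC templates; UC cells carry ~1.5x brighter organelle staining,
    mirroring the study's finding of higher UC marker expression."""
    return {
        "BM": default_cell_spec(image_shape, amplitude_scale=1.0),
        "UC": default_cell_spec(image_shape, amplitude_scale=1.5),
    }


def radial_control_spec(
    bias_a: float,
    bias_b: float,
    image_shape: tuple[int, int] = (192, 192),
    rng_seed: int = 0,
) -> SyntheticCellSpec:
    """Two punctate markers with given radial biases in one cell.

    This is the positive/negative control for the radial Kolmogorov-Smirnov
    procedure: many small blobs so that foreground pixels approximate
    independent draws from the radial law.
    """
    h, w = image_shape
    center = (h / 2.0, w / 2.0)
    cell = Ellipse(center, (0.42 * h, 0.34 * w), rotation_deg=0.0)
    nucleus = Ellipse(center, (0.12 * h, 0.10 * w), 0.0)
    markers = [
        MarkerSpec("radial_a", n_blobs=300, blob_sigma_px=1.2, amplitude=3000, radial_bias=bias_a),
        MarkerSpec("radial_b", n_blobs=300, blob_sigma_px=1.2, amplitude=3000, radial_bias=bias_b),
    ]
    return SyntheticCellSpec(
        image_shape=image_shape,
        cell_ellipse=cell,
        nucleus_ellipse=nucleus,
        markers=markers,
        background_level=10.0,
        gaussian_noise_sd=5.0,
        poisson_noise=True,
        rng_seed=rng_seed,
    )


def build_population_from_config(cfg: Mapping) -> list[CellRecord]:
    """Build a population from a YAML-style mapping (used by the CLI).

    Recognized keys: ``seed`` (int), ``image_shape`` ([H, W]),
    ``n_per_group`` (mapping group -> count), ``amplitude_scale`` (mapping
    group -> factor, default BM 1.0 / UC 1.5), ``vary_geometry`` (bool).
    """
    seed = int(cfg.get("seed", 0))
    image_shape = tuple(cfg.get("image_shape", (256, 256)))
    n_per_group = {str(g): int(n) for g, n in cfg.get("n_per_group", {"BM": 7, "UC": 7}).items()}
    scales = cfg.get("amplitude_scale", {})
    specs = {}
    for i, group in enumerate(sorted(n_per_group)):
        default_scale = 1.0 + 0.5 * (group == "UC")
        specs[group] = default_cell_spec(
            image_shape, amplitude_scale=float(scales.get(group, default_scale))
        )
    return generate_population(
        n_per_group, specs, seed=seed, vary_geometry=bool(cfg.get("vary_geometry", True))
    )
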