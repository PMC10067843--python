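import numpy as np
import pytest

from spatnet import BinaryMask, ChannelImage, Ellipse, MarkerSpec, SyntheticCellSpec, generate_cell


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_channel(pixels, name="marker", pixel_size=0.1083):
    return ChannelImage(np.asarray(pixels, dtype=float), marker_name=name, pixel_size_um=pixel_size)


def make_mask(pixels):
    return BinaryMask(np.asarray(pixels, dtype=bool))


def full_mask(shape):
    return BinaryMask(np.ones(shape, dtype=bool))


def two_marker_spec(seed=0, overlap=0.0, noise_sd=0.0, poisson=False, n_blobs=40):
    """Small 96x96 two-marker cell used across module tests."""
    cell = Ellipse((48, 48), (36, 28), rotation_deg=10.0)
    nucleus = Ellipse((48, 48), (11, 9), rotation_deg=10.0)
    return SyntheticCellSpec(
        image_shape=(96, 96),
        cell_ellipse=cell,
        nucleus_ellipse=nucleus,
        markers=[
            MarkerSpec("A", n_blobs=n_blobs, blob_sigma_px=2.0, amplitude=3000.0),
            MarkerSpec("B", n_blobs=n_blobs, blob_sigma_px=2.0, amplitude=3000.0),
        ],
        overlap_targets={("A", "B"): overlap} if overlap else {},
        background_level=10.0,
        gaussian_noise_sd=noise_sd,
        poisson_noise=poisson,
        rng_seed=seed,
    )


@pytest.fixture()
def small_cell():
    return generate_cell(two_marker_spec(seed=7, overlap=0.5, noise_sd=5.0, poisson=True), "t01", "BM")
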