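import numpy as np
import pytest

from adipophen import synthetic


@pytest.fixture(scope="session")
def ct_phantom():
    """A mid-fat, low-noise CT phantom shared across read-only tests."""
    return synthetic.make_ct_phantom(
        fat_fraction=0.30, noise_sigma_hu=10.0, seed=42, geometry_seed=7
    )


@pytest.fixture(scope="session")
def mosaic():
    """A noise-free adipocyte mosaic with exact per-cell truth."""
    return synthetic.make_adipocyte_mosaic(
        n_cells=200, mean_area_um2=2500.0, pixel_size_um=1.0, noise_sd=0.0, seed=5
    )


@pytest.fixture(scope="session")
def pet_phantom():
    return synthetic.make_pet_phantom(seed=11, geometry_seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
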