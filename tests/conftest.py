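import numpy as np
import pytest

from spatglia import syndata


@pytest.fixture(scope="session")
def small_study():
    """Scaled-down 8-sample study shared across read-only tests."""
    return syndata.simulate_study(seed=11, n_rows=18, n_cols=20,
                                  n_genes=600, n_region_markers=30)


@pytest.fixture(scope="session")
def two_group():
    """Flat two-group dataset with DAM spikes at fold 2."""
    return syndata.two_group_dataset(n_spots_per_group=250, n_genes=800,
                                     fold=2.0, seed=21)


@pytest.fixture(scope="session")
def plaque_sample():
    """Single AD-7M sample with a plaque-blob driver gene and its image."""
    sdata = syndata.plaque_dataset(seed=7)
    image = syndata.render_plaque_image(sdata, "Cst7",
                                        image_shape=(256, 256),
                                        psf_sigma=3.0, noise_sd=0.02, seed=8)
    return sdata, image


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
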