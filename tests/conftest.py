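import warnings

import numpy as np
import pytest

import blastoquant as bq


@pytest.fixture(autouse=True)
def _quiet_fit_warnings():
    """Surface-fit fallback warnings are expected on tiny point sets."""
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*fallback.*", category=UserWarning
        )
        yield


@pytest.fixture
def small_movie():
    """One deterministic 3-embryo movie with truth (noisy conditions)."""
    params = bq.SimParams(seed=11, n_embryos=3, n_frames=10,
                          reposition_prob=0.05)
    nuclei, tracks, truth = bq.simulate_embryo_series(params)
    return params, nuclei, tracks, truth


@pytest.fixture
def clean_movie():
    """Noise-free movie: no intensity noise, no z decay, no centroid noise."""
    channels = [bq.ChannelModel(4.0, 4.6, -0.02, 0.02, 0.0)]
    params = bq.SimParams(
        seed=3, n_embryos=2, n_frames=6, division_rate=0.1,
        channel_model=channels, z_decay=0.0, reposition_prob=0.0,
        centroid_noise_sd=0.0,
    )
    nuclei, tracks, truth = bq.simulate_embryo_series(params)
    return params, nuclei, tracks, truth


def true_radial(nuclei, params):
    """Normalized radius w.r.t. the generator's known ellipsoid."""
    axes = np.asarray(params.ellipsoid_axes)
    center = axes + 10.0
    p = nuclei[["x_um", "y_um", "z_um"]].values
    return np.sqrt(np.sum(((p - center) / axes) ** 2, axis=1))
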