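import numpy as np
import pytest

from hpalign import CalibrationConfig, SearchParams, build_model, load_scale


@pytest.fixture(scope="session")
def kd():
    return load_scale("kyte_doolittle")


@pytest.fixture()
def rng():
    return np.random.default_rng(20130)


@pytest.fixture(scope="session")
def small_model():
    """A quick low-confidence hydropathy model for workflow tests."""
    cfg = CalibrationConfig(
        profile_lengths=(40, 60, 80, 100),
        pairs_per_length=400,
        seed=123,
        params=SearchParams(),
    )
    return build_model(cfg)


def random_hydropathy_like(rng, length, smooth=7):
    """A smooth random profile with hydropathy-like amplitude (~[-3, 3])."""
    raw = rng.normal(0.0, 2.0, size=length + smooth - 1)
    kernel = np.ones(smooth) / smooth
    return np.convolve(raw, kernel, mode="valid")
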