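import numpy as np
import pytest

from gxecross.simulate import GenParams, SimConfig, gen_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """One modest strong-differential-susceptibility cohort for reuse."""
    return gen_cohort(SimConfig(n=400, seed=42))


@pytest.fixture(scope="session")
def paper_scale_cohort():
    """One cohort at the study's sample size under the default model."""
    return gen_cohort(SimConfig(seed=2024))


def make_cohort(n=400, seed=0, **kwargs):
    return gen_cohort(SimConfig(n=n, seed=seed, **kwargs))


def noiseless_config(n=400, seed=0, **kwargs):
    return SimConfig(n=n, seed=seed, sigma=0.0, **kwargs)


__all__ = ["make_cohort", "noiseless_config", "GenParams"]
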