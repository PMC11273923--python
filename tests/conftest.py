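import numpy as np
import pytest
from hypothesis import settings

from agenas import spos

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")
from agenas.synth_opg import SynthConfig, generate_sample, sample_ages


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_plan():
    """A 4-layer supernet plan small enough for exact-equality checks."""
    return spos.SupernetPlan(
        stem_cout=8, couts=(8, 8, 16, 16), strides=(1, 2, 1, 2),
        expands=(1.0, 2.0, 2.0, 2.0), head_cout=32, num_classes=76,
        input_channels=1)


@pytest.fixture(scope="session")
def toy_plan_2layer():
    """A 2-layer plan whose 9-path space can be enumerated exhaustively."""
    return spos.SupernetPlan(
        stem_cout=8, couts=(8, 8), strides=(1, 2), expands=(1.0, 2.0),
        head_cout=16, num_classes=10, input_channels=1)


def make_synth_arrays(n, seed, image_size=64, noise_sd=0.05,
                      sampler="uniform"):
    """In-memory synthetic dataset: (images (N,1,S,S), integer ages)."""
    cfg = SynthConfig(n=n, image_size=image_size, noise_sd=noise_sd,
                      age_sampler=sampler, seed=seed)
    gen = np.random.default_rng(seed)
    ages = sample_ages(cfg, gen)
    images = np.stack([generate_sample(int(a), gen, cfg).image[None]
                       for a in ages])
    return images, ages


@pytest.fixture(scope="session")
def small_synth():
    return make_synth_arrays(n=48, seed=99, image_size=32)
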