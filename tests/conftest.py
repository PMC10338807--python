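import numpy as np
import pytest

from nodulenet import NoduleNet, PhantomConfig, init_weights, make_samples, tiny_config


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_model():
    """Small 4-stage network on 16^3 inputs, deterministic weights."""
    return init_weights(NoduleNet(tiny_config(), head_hidden=32, dr_hidden=16),
                        seed=0)


@pytest.fixture(scope="session")
def clean_phantoms():
    """Noise-free 16^3 phantoms: one reader, exact ratings, exact masks."""
    cfg = PhantomConfig(n_nodules=24, readers=1, cube_side=16,
                        rating_noise_sd=0.0, mask_jitter=0,
                        semantic_noise=False, seed=3)
    return cfg, make_samples(cfg)


def pair_of(sample):
    from nodulenet.preprocess import ROIPair

    return ROIPair(sample.nodule_cube, sample.mask_cube)
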