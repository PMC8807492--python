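import dataclasses

import numpy as np
import pytest

from mrmtex.phantom import PhantomConfig, generate_phantom


def small_phantom_config(**overrides) -> PhantomConfig:
    """96x96 phantom, fast enough for per-test generation."""
    base = dict(
        image_shape=(96, 96),
        voxel_spacing=(90.0, 90.0),
        n_lobules=20,
        lobule_radius_range=(5.0, 11.0),
        seed=0,
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def default_phantom():
    """One default-config phantom pair (seed 1), shared across tests."""
    return generate_phantom(PhantomConfig(seed=1))


@pytest.fixture()
def small_phantom():
    return generate_phantom(small_phantom_config(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def clone(cfg: PhantomConfig, **overrides) -> PhantomConfig:
    return dataclasses.replace(cfg, **overrides)
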