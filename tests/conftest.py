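import numpy as np
import pytest
from hypothesis import settings

import shiftsr as s

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_schedule():
    """The package defaults: T=15, p=0.3, gamma=2, kappa=0.04, beta_T=0.9999."""
    return s.build_schedule()


@pytest.fixture(scope="session")
def small_pair():
    """One 32x32 phantom pair at x4 degradation."""
    return s.make_dataset(1, s.PhantomSpec(size=32, seed=11), s.DegradeSpec(4, 4), seed=11)[0]


@pytest.fixture(scope="session")
def tiny_pairs_16():
    """Four 16x16 phantom pairs (fast fixtures for NN tests)."""
    return s.make_dataset(4, s.PhantomSpec(size=16, seed=3), s.DegradeSpec(4, 4), seed=3)


@pytest.fixture(scope="session")
def tiny_spec():
    """A small denoiser spec that still exercises every code path."""
    return s.DenoiserSpec(base_channels=8, depth=2, use_windowed_attention=True,
                          window_size=4, time_embed_dim=16, seed=1)
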