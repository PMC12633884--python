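"""Shared fixtures: small stimulus ensembles reused across test modules."""

import numpy as np
import pytest

from duotap import SimConfig, generate_hum_set, generate_ran_set


@pytest.fixture(scope="session")
def hum_set_small():
    """20 HUM stimuli selected from a 60-run ensemble (b = 1.0)."""
    cfg = SimConfig.study_default(b=1.0, sigma=0.3, seed=0)
    return generate_hum_set(cfg, reps=60, keep=20)


@pytest.fixture(scope="session")
def ran_set_small(hum_set_small):
    """RAN surrogates of ``hum_set_small`` (100 shuffles per source)."""
    return generate_ran_set(hum_set_small, shuffles=100)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
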