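import dataclasses

import numpy as np
import pytest

from turkeydem import McmcConfig, studylike_config, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study (~60 hen-years) shared across tests."""
    cfg = studylike_config(seed=11)
    cfg = dataclasses.replace(cfg, n_hens_per_year={2017: 30, 2018: 30})
    study, truth = simulate_study(cfg)
    return study, truth, cfg


@pytest.fixture(scope="session")
def medium_study():
    """A study-scale simulation (~155 hen-years per season defaults)."""
    cfg = studylike_config(seed=23)
    study, truth = simulate_study(cfg)
    return study, truth, cfg


@pytest.fixture()
def quick_mcmc():
    """Short, doubling-free sampler settings for smoke-level fits."""
    return McmcConfig(n_chains=2, n_warmup=300, n_samples=300, seed=5, max_doublings=0)
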