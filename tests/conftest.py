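import logging

import numpy as np
import pytest
from hypothesis import settings

from sharedreach.pipeline import RunConfig, run_pipeline
from sharedreach.simulate import SimConfig, generate_dyad_experiment

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")

logging.disable(logging.WARNING)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_experiment():
    """A small but complete synthetic experiment (raw trials + ratings)."""
    cfg = SimConfig(n_dyads=4, trials_per_session=5, n_sessions_per_condition=2, seed=7)
    trials, ratings = generate_dyad_experiment(cfg)
    return cfg, trials, ratings


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-configuration pipeline run (the study conditions)."""
    out = tmp_path_factory.mktemp("run")
    return run_pipeline(RunConfig(seed=0), out_dir=out)
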