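import numpy as np
import pandas as pd
import pytest

from twostep import (AgentParams, HybridAgent, PopulationSpec, build_stay_design,
                     default_config, simulate_session, synth_population,
                     trials_to_frame)
from twostep.agents import make_degenerate_agent


def simulate_cohort(agent_factory, n_subjects, config=None, seed=0):
    """Simulate n_subjects independent sessions and stack the logs."""
    if config is None:
        config = default_config()
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_subjects):
        agent = agent_factory(i)
        recs = simulate_session(agent, config, subject=f"s{i:04d}",
                                rng=np.random.default_rng(rng.integers(2 ** 63)))
        frames.append(trials_to_frame(recs))
    return pd.concat(frames, ignore_index=True)


def hybrid_cohort(n_subjects, w, seed=0, config=None, **params):
    return simulate_cohort(
        lambda i: HybridAgent(AgentParams(w=w, **params)),
        n_subjects, config=config, seed=seed)


@pytest.fixture(scope="session")
def uniform_cohort60():
    """60 uniform-random subjects, standard 2x100 session."""
    return simulate_cohort(
        lambda i: make_degenerate_agent("uniform_random"), 60, seed=101)


@pytest.fixture(scope="session")
def recovery_cohort():
    """200 hybrid subjects with w ~ U(0,1); trials plus covariates."""
    spec = PopulationSpec(n_subjects=200, w_dist="uniform")
    trials, covariates = synth_population(spec, seed=202)
    return trials, covariates


@pytest.fixture(scope="session")
def recovery_rows(recovery_cohort):
    trials, _ = recovery_cohort
    return build_stay_design(trials)
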