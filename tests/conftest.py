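import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning)

from horizontask import (
    ObserverConfig,
    TaskConfig,
    simulate_session,
    study_agent_params,
)


@pytest.fixture(scope="session")
def observer():
    return ObserverConfig()


@pytest.fixture(scope="session")
def small_sessions(observer):
    """Two sessions per condition for one animal; enough for metrics/designs."""
    out = []
    for cond in ("partial", "complete"):
        cfg = TaskConfig(feedback=cond, trials_per_session=50)
        params = study_agent_params(cond)
        for k in range(2):
            out.append(
                simulate_session(f"A_{cond}_{k}", "A", cfg, params, observer,
                                 rng_seed=100 + k + (cond == "complete") * 10)
            )
    return out


def naive_posterior_mean(observations, config):
    """Independent enumeration oracle: direct products, no log space.

    Re-derives the posterior over candidate means with plain double loops
    over grid x observations and returns its mean.
    """
    post = np.array(config.prior, dtype=float).copy()
    for j, mu in enumerate(config.mean_grid):
        # per-mu likelihood normalized over the outcome support
        dens = np.exp(-((config.outcome_support - mu) ** 2) / (2 * config.sigma**2))
        dens = dens / dens.sum()
        for x in observations:
            xi = int(np.argmin(np.abs(config.outcome_support - x)))
            post[j] *= dens[xi]
    post /= post.sum()
    return float(post @ config.mean_grid)


def naive_predictive(observations, config):
    """Enumeration oracle for the posterior predictive distribution."""
    post = np.array(config.prior, dtype=float).copy()
    lik = np.zeros((len(config.outcome_support), len(config.mean_grid)))
    for j, mu in enumerate(config.mean_grid):
        dens = np.exp(-((config.outcome_support - mu) ** 2) / (2 * config.sigma**2))
        lik[:, j] = dens / dens.sum()
        for x in observations:
            xi = int(np.argmin(np.abs(config.outcome_support - x)))
            post[j] *= lik[xi, j]
    post /= post.sum()
    pred = lik @ post
    return pred / pred.sum()
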