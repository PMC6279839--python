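import numpy as np
import pytest

from asynchmm.simulate import (default_ground_truth, simulate_cohort,
                               simulate_counts, simulate_states)


@pytest.fixture(scope="session")
def ground_truth():
    return default_ground_truth()


@pytest.fixture(scope="session")
def sim_5k(ground_truth):
    """5000 windows from the reference chain, with the true state path."""
    states = simulate_states(ground_truth.params, 5000, seed=101)
    series = simulate_counts(ground_truth.params, states, seed=102,
                             exposure_rate=ground_truth.exposure_rate)
    return series


@pytest.fixture(scope="session")
def small_cohort(ground_truth):
    """Ten short synthetic patients for model/CV plumbing tests."""
    return simulate_cohort(ground_truth, n_sequences=10, n_windows=120,
                           seed=77)


def random_params(rng, K):
    """A random valid parameter set with strictly positive entries."""
    from asynchmm.types import HmmParams
    pi = rng.dirichlet(np.ones(K) * 2.0)
    A = rng.dirichlet(np.ones(K) * 2.0, size=K)
    lam = np.sort(rng.lognormal(mean=1.0, sigma=1.0, size=K)) + 0.1
    return HmmParams(pi=pi, A=A, lam=lam).validate()
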