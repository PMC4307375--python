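import numpy as np
import pytest

from biobridge import (
    ModelSpec,
    SamplerSettings,
    TrialSummary,
    load_example_trials,
)


@pytest.fixture(scope="session")
def example_trials():
    return load_example_trials()


@pytest.fixture(scope="session")
def toy_trials():
    """Two small trials: B=(4,6), B_T=(2,3), X=(4,6), X_T=(2,3)."""
    return [
        TrialSummary("t1", n_t=10, n_c=10, b_t=2, b_c=2, x_t=2, x_c=2),
        TrialSummary("t2", n_t=10, n_c=10, b_t=3, b_c=3, x_t=3, x_c=3),
    ]


@pytest.fixture(scope="session")
def fast_settings():
    """Short single-chain run for tests that only need a rough posterior."""
    return SamplerSettings(n_chains=1, n_burnin=600, n_iter=1500, thin=1)


@pytest.fixture(scope="session")
def medium_settings():
    return SamplerSettings(n_chains=2, n_burnin=2000, n_iter=8000, thin=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_posterior(beta0, beta, phi_b=None, trial_ids=("a",)):
    """Hand-built PosteriorDraws for closed-form prediction tests."""
    from biobridge import PosteriorDraws

    beta0 = np.asarray(beta0, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = len(beta0)
    if phi_b is None:
        phi_b = np.full((n, len(trial_ids)), 0.5)
    return PosteriorDraws(
        beta0=beta0,
        beta=beta,
        phi_b=phi_b,
        trial_ids=tuple(trial_ids),
        n_chains=1,
        n_burnin=0,
        n_kept=n,
        seed=0,
    )
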