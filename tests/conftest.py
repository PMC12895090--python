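import numpy as np
import pytest

import streammove as sm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20201115)


@pytest.fixture(scope="session")
def small_reach():
    """A reduced reach (10 sections, 5 occasions) for fast structural tests."""
    return sm.generate_reach(S=10, T=5, seed=7)


@pytest.fixture(scope="session")
def standard_replicates():
    """The standard synthetic fit dataset: 300 replicates at the reference
    truth (beta0 = ln 0.3 per day, beta_size = 0.4, phi = 0.5)."""
    return sm.simulate_replicates(
        300, np.log(0.3), {"body_size": 0.4}, 0.5, seed=1
    )


@pytest.fixture(scope="session")
def standard_fit(standard_replicates):
    """Marginalized fit of the standard synthetic dataset (4 chains x 4000
    iterations, 1500 burn-in, thin 5)."""
    cfg = sm.SamplerConfig(n_iter=4000, burn_in=1500, thin=5, seed=1)
    return sm.sample_posterior(standard_replicates, sm.ModelConfig(), cfg)


@pytest.fixture(scope="session")
def tiny_study():
    """A complete emitted 2-species synthetic study, small enough for I/O
    and pipeline tests."""
    truths = [
        sm.SpeciesTruth(
            "creek_chub", 120, 92.4, 21.1, np.log(0.25),
            {"body_size": 0.3}, phi=0.35, p_detect=0.6,
            recruits_per_occasion=10,
        ),
        sm.SpeciesTruth(
            "green_sunfish", 80, 84.6, 18.4, np.log(0.25),
            {"body_size": 0.0}, phi=0.35, p_detect=0.6,
            recruits_per_occasion=6,
        ),
    ]
    return sm.generate_study(truths, seed=11, S=20, T=8)
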