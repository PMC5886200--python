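import numpy as np
import pytest

from matfet import simgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort():
    """A modest complete+patterned cohort with nonzero effects."""
    cfg = simgen.SimConfig(
        n_individuals=4000, eaf=0.3, m=0.05, f=0.03, rho=0.1, seed=99
    )
    return simgen.simulate_cohort(cfg)


@pytest.fixture
def complete_cohort():
    """All records in the BOTH pattern (no missingness)."""
    cfg = simgen.SimConfig(
        n_individuals=20_000,
        eaf=0.3,
        m=0.05,
        f=0.03,
        rho=0.1,
        pattern_fractions=(0.0, 0.0, 1.0),
        seed=7,
    )
    return simgen.simulate_cohort(cfg)
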