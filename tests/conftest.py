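import numpy as np
import pandas as pd
import pytest

from ccfrisk.simulate import preset_paper_like, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared by I/O, model and pipeline tests."""
    cfg = preset_paper_like(seed=424, n_patients=120, n_genes=60)
    cohort, truth = simulate_cohort(cfg)
    return cohort, truth


@pytest.fixture
def surv6():
    """Six-subject survival fixture with an interior Cox optimum."""
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 0, 1, 1, 0, 1])
    x = np.array([1.0, 0.0, 0.0, 1.0, 1.0, 0.0])
    return x, time, event


def exp_surv(rng, lp, baseline=0.03, admin=84.0, censor_mean=150.0):
    """Exponential PH survival draw with administrative + random censoring."""
    t = rng.exponential(1.0 / (baseline * np.exp(lp)))
    c = np.minimum(rng.exponential(censor_mean, size=len(lp)), admin)
    return np.minimum(t, c), (t <= c).astype(int)
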