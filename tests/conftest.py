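import numpy as np
import pandas as pd
import pytest

from relcov import SimConfig, simulate_cohort
from relcov.workflows import am_equilibrium_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def am_cohort_mid():
    """A mid-size assortative-mating cohort shared across tests.

    10 generations at n = 10,000 with spousal correlation 0.24 and
    random-mating heritability 0.75 -- large enough that equilibrium
    variance ratios and realised spousal correlations are stable.
    """
    cfg = SimConfig(n_individuals=10_000, n_causal=100, n_markers=100,
                    h2_rm=0.75, spousal_r=0.24, n_generations=10,
                    sibs_per_family=2, seed=42)
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def am_study_large():
    """The full AM equilibrium pipeline at n = 20,000 (shared)."""
    cfg = SimConfig(n_individuals=20_000, n_causal=100, n_markers=100,
                    h2_rm=0.75, spousal_r=0.24, n_generations=10,
                    sibs_per_family=3, seed=1)
    return cfg, am_equilibrium_study(cfg)


@pytest.fixture(scope="session")
def twin_cohort():
    """Random-mating cohort with MZ/DZ twin families, ACE architecture."""
    cfg = SimConfig(n_individuals=8_000, n_causal=80, n_markers=80,
                    h2_rm=0.6, c2=0.1, spousal_r=0.0, n_generations=1,
                    sibs_per_family=2, twin_fractions=(0.25, 0.25),
                    seed=7)
    return cfg, simulate_cohort(cfg)


def standardized_phenotype(cohort, ids=None):
    comp = cohort.components.set_index("iid")
    y = (comp["phenotype"] if ids is None
         else comp.loc[ids, "phenotype"]).to_numpy()
    return (y - y.mean()) / y.std(ddof=1)
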