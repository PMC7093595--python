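import numpy as np
import pytest

from mtsim import (CohortConfig, IndividualParameters, PKConstants,
                   PopulationModel, generate_cohort)
from mtsim.prep import filter_cohort


@pytest.fixture(scope="session")
def consts():
    return PKConstants()


@pytest.fixture(scope="session")
def ref_params():
    """Published in-sample fixed effects."""
    return IndividualParameters(Base=2.34, k_tr=0.148, gamma=0.769, slope=0.242)


@pytest.fixture(scope="session")
def ref_pop():
    return PopulationModel.reference()


@pytest.fixture(scope="session")
def small_cohort(ref_pop):
    """Six virtual patients with short follow-up; shared across tests."""
    cfg = CohortConfig(n_patients=6, followup_range=(150.0, 220.0), seed=42)
    return generate_cohort(ref_pop, cfg, seed=42)


@pytest.fixture(scope="session")
def small_cohort_filtered(small_cohort):
    recs, _ = filter_cohort(small_cohort)
    return recs


@pytest.fixture(scope="session")
def noiseless_cohort(ref_pop, consts):
    """Tiny cohort with no IIV, no noise, no infections, no titration:
    every patient follows the population-typical trajectory exactly."""
    pop = PopulationModel(theta=ref_pop.theta, omega2=np.zeros(4), sigma2=0.0)
    cfg = CohortConfig(n_patients=3, followup_range=(120.0, 160.0),
                       infection_rate=0.0, titration=False, obs_jitter=0.0,
                       seed=5)
    return generate_cohort(pop, cfg, consts, seed=5)
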