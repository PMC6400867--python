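import numpy as np
import pandas as pd
import pytest

from stresscomp.accelerometry import CutPoints
from stresscomp.bhlm import McmcConfig, ModelSpec, build_design, run_mcmc
from stresscomp.synthetic import CohortConfig, simulate_cohort_tables, simulate_observations


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cuts():
    return CutPoints(sb_max=180, mvpa_min=757, epoch_length_s=15)


@pytest.fixture(scope="session")
def small_tables():
    """A small but complete synthetic dataset shared across tests."""
    config = CohortConfig(n_ig=8, n_cg=4, seed=77, epoch_length_s=60)
    return simulate_cohort_tables(config)


OBS_COLUMNS = ["y", "id", "group", "gender", "season", "timepoint",
               "sb", "lpa", "mvpa"]


@pytest.fixture
def empty_observations():
    return pd.DataFrame(columns=OBS_COLUMNS)


QUICK_MCMC = McmcConfig(chains=3, iterations=1500, burn_in=500, thinning=5, seed=99)


@pytest.fixture(scope="session")
def fitted_small_model():
    """One quick fitted AUCi-style model reused by diagnostics tests."""
    rng = np.random.default_rng(4242)
    obs = simulate_observations(
        n_ig=10, n_cg=6, seasons=("fall", "spring"),
        composition_slopes={"CG": (0.5, -0.5, 0.8), "IG": (-0.6, -0.9, 0.7)},
        rng=rng, sigma_y=0.4, mixture_concentration=10.0,
    )
    spec = ModelSpec.from_id("bhlm2")
    design = build_design(obs, spec)
    chains = run_mcmc(design, spec.prior_set, QUICK_MCMC)
    return design, chains, spec
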