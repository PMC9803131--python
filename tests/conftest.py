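import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import expowin as e
from expowin import io as eio
from expowin.microsim import LifeTable, SimulationConfig
from expowin.uncertainty import SimulationInputs

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def truth():
    """Default mobile-transition truth world."""
    return e.make_truth(e.TruthConfig(seed=7))


@pytest.fixture(scope="session")
def printed_table():
    """Parsed packaged printed transition table."""
    return eio.read_transition_table(eio.packaged_transition_table())


@pytest.fixture(scope="session")
def both_matrix(printed_table):
    return printed_table["both"]["matrix"].probs


@pytest.fixture(scope="session")
def small_world(both_matrix):
    """Small simulation-input bundle: 2 sexes x 3 age groups."""
    rng = np.random.default_rng(0)
    groups = ["40-44", "45-49", "50-54"]
    pop = pd.DataFrame([{"sex": s, "age_group": g, "count": 1000}
                        for s in ("female", "male") for g in groups])
    prev = {(s, g): rng.dirichlet(np.ones(6) * 3)
            for s in ("female", "male") for g in groups}
    lt = LifeTable.from_function(
        lambda sex, a, y: min(1.0, 3e-5 * np.exp(0.09 * a)), years=(0,))
    return SimulationInputs(population=pop, prevalence=prev,
                            matrices={"female": both_matrix,
                                      "male": both_matrix},
                            life_table=lt)


@pytest.fixture
def single_stratum_pop():
    return pd.DataFrame([{"sex": "female", "age_group": "40-44",
                          "count": 1}])


def prevalence_frame(vec, sex="female", age_group="40-44"):
    return pd.DataFrame([{"sex": sex, "age_group": age_group,
                          "category": k, "proportion": p}
                         for k, p in enumerate(vec)])


@pytest.fixture
def ten_year_config():
    return SimulationConfig(window_start=2002, window_end=2011, n=50_000,
                            seed=11)
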