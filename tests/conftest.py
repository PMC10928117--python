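import numpy as np
import pandas as pd
import pytest

from hwle.model import MultiStateModel, ParameterVector, TransitionModelSpec
from hwle.panel import from_dataframe
from hwle.simulate import (
    config_from_scenario,
    load_scenario,
    simulate_cohort,
    true_model_from_scenario,
)
from hwle.states import StateSpace, three_state_space


@pytest.fixture(scope="session")
def two_state_space() -> StateSpace:
    allowed = np.zeros((2, 2), dtype=bool)
    allowed[0, 1] = True
    return StateSpace(labels=("alive", "dead"), death=1, allowed=allowed)


@pytest.fixture(scope="session")
def const_mortality_params(two_state_space) -> ParameterVector:
    """Two-state, constant hazard 0.1/year (age effect constrained off)."""
    spec = TransitionModelSpec(
        state_space=two_state_space, constraints=(("alive-dead", "age"),)
    )
    return ParameterVector(spec, np.log([0.1]), np.zeros(1), np.zeros((1, 0)))


@pytest.fixture(scope="session")
def age_only_params() -> ParameterVector:
    """3-state generating parameters of the default study conditions."""
    spec = TransitionModelSpec(state_space=three_state_space())
    return ParameterVector(
        spec,
        np.log([0.08, 0.001, 0.35, 0.0035]),
        np.log([1.07, 1.06, 0.86, 1.10]),
        np.zeros((4, 0)),
    )


@pytest.fixture(scope="session")
def recovery_scenario():
    return load_scenario("recovery")


@pytest.fixture(scope="session")
def small_cohort(recovery_scenario):
    """A modest simulated cohort shared across read-only tests."""
    tm = true_model_from_scenario(recovery_scenario)
    cfg = config_from_scenario(recovery_scenario, n_subjects=500)
    panel, truth = simulate_cohort(tm, cfg, seed=20240)
    return panel, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Age + one-covariate fit on the shared cohort."""
    panel, _ = small_cohort
    model = MultiStateModel(
        covariates=("pain",),
        constraints=(("HW-dead", "pain"), ("nHW-HW", "pain"), ("nHW-dead", "pain")),
    )
    return model.fit(panel)


@pytest.fixture()
def simple_panel_df() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": ["a", "a", "a"],
            "age": [51.0, 53.0, 55.0],
            "state": [1, 1, 2],
        }
    )


@pytest.fixture()
def make_panel():
    def _make(df, **kwargs):
        return from_dataframe(df, three_state_space(), **kwargs)

    return _make
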