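"""Shared fixtures: hand-built micro-databases and session-scoped
analyses of the canonical synthetic scenarios (which several tests share
because they are the expensive part of the suite)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hypothesis_settings

from netcohort import ScenarioConfig, SyntheticDatabase
from netcohort import experiments as ex

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")


def make_database(persons, exposures=None, indications=None,
                  hospitalizations=None, outcomes=None, covariates=None,
                  n_outcomes=3, n_covariates=4) -> SyntheticDatabase:
    """Assemble a SyntheticDatabase from plain row dicts (tests only)."""
    def frame(rows, cols):
        return pd.DataFrame(rows or [], columns=cols)
    return SyntheticDatabase(
        database_id="db_test",
        persons=frame(persons, ["person_id", "birth_year", "sex",
                                "observation_start", "observation_end"]),
        covariates=frame(covariates, ["person_id", "covariate_id", "value"]),
        exposures=frame(exposures, ["person_id", "drug_class", "start_date"]),
        indications=frame(indications, ["person_id", "date"]),
        hospitalizations=frame(hospitalizations, ["person_id", "date"]),
        outcomes=frame(outcomes, ["person_id", "outcome_id", "date",
                                  "setting"]),
        truth={"true_log_hr": [0.0] * n_outcomes,
               "bias": [0.0] * n_outcomes,
               "treatment_intercept": 0.0},
        n_covariates=n_covariates,
    )


def survival_frame(times, events, arms):
    t = np.asarray(times, dtype=float)
    return pd.DataFrame({
        "person_id": np.arange(len(t)),
        "arm": arms,
        "time": t,
        "event": np.asarray(events, dtype=np.int8),
        "person_years": t / 365.25,
    })


@pytest.fixture(scope="session")
def confounded_analysis():
    """The measured-confounding reference scenario, fully analysed:
    20,000 persons, 20 binary covariates each shifting treatment log-odds
    and outcome log-hazard by 0.3, 50 true-null controls, no injected bias."""
    return ex.analyze_single_database(ex.confounded_scenario(2026))


@pytest.fixture(scope="session")
def randomized_analysis():
    """Coin-flip treatment assignment (P(target)=0.4), same covariates."""
    return ex.analyze_single_database(ex.randomized_scenario(2026),
                                      fit_controls=False)
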