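"""Shared fixtures: synthetic cohorts, tariffs, life table, configs."""

import dataclasses

import numpy as np
import pytest

import lenscea as lc


@pytest.fixture(scope="session")
def unit_costs():
    return lc.default_unit_costs()


@pytest.fixture(scope="session")
def life_table():
    return lc.default_life_table()


@pytest.fixture(scope="session")
def trial_cohort():
    """Default-calibrated n=285 cohort: (observed, ground truth)."""
    return lc.generate_trial(lc.GeneratorParams(n=285, seed=1))


@pytest.fixture(scope="session")
def big_cohort():
    """n=10 000 complete cohort (no missingness) for parameter recovery."""
    params = lc.GeneratorParams(n=10000, seed=7)
    rng = np.random.default_rng(params.seed)
    cohort = lc.generate_cohort(params, rng)
    lc.assign_treatment(cohort, seed=params.seed + 10)
    lc.simulate_outcomes(cohort, params, rng)
    return cohort, params


@pytest.fixture()
def fast_config():
    return dataclasses.replace(lc.AnalysisConfig(), bootstrap_reps=60,
                               psa_iterations=40, seed=3)


@pytest.fixture(scope="session")
def fitted_inputs(trial_cohort, unit_costs):
    obs, _ = trial_cohort
    return lc.fit_model_inputs(obs, unit_costs)
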