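"""Shared fixtures: small synthetic datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import thermocog as tc


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete study: 12 counties, 2 years."""
    return tc.SyntheticConfig(seed=42, n_counties=12, grid_shape=(3, 4),
                              n_months=24, n_subjects=500)


@pytest.fixture(scope="session")
def small_linked(small_config):
    linked, truth, _ = tc.generate_linked(small_config)
    return linked, truth


@pytest.fixture(scope="session")
def noiseless_quadratic_linked():
    """Noiseless data from a known quadratic response g(T) = -0.01 (T+7)^2."""
    truth = tc.SyntheticTruth(
        alpha0=20.0, beta0_time=0.0,
        response=tc.synthetic.QuadraticResponse(peak=-7.0, curvature=-0.01),
        beta_precip=0.0, beta_pm25=0.0,
        sd_county_structured=0.0, sd_county_iid=0.0, sd_county_slope=0.0,
        sd_month=0.0, sd_month_slope=0.0, sd_interaction=0.0,
        sd_interaction_slope=0.0, sd_nu=0.0, sd_epsilon=0.0)
    cfg = tc.SyntheticConfig(seed=7, n_counties=12, grid_shape=(3, 4),
                             n_months=24, n_subjects=600, truth=truth)
    linked, _, _ = tc.generate_linked(cfg)
    return linked, truth


@pytest.fixture
def fixed_only_spec():
    """ModelSpec with every random-effect block disabled."""
    return tc.ModelSpec(
        temperature_term=tc.TemperatureLinear(),
        county_bym_intercept=False, county_slope=False,
        month_rw_intercept=False, month_slope=False,
        interaction=False, interaction_slope=False, global_time_rw=False)


@pytest.fixture
def toy_records():
    """Hand-built 10-row record table: 2 missing-covariate rows, 1 row with
    only four domains, 1 duplicate id, 6 clean."""
    base = {
        "county_id": "c1", "year": 2010, "month": 6,
        "global_score": 25.0,
        **{f"score_{d}": 5.0 for d in tc.data_model.DOMAINS},
        "gender": "female", "age": 80, "residence": "rural",
        "education": "low", "income": "low", "ethnicity": "Han",
    }
    rows = []
    for i in range(10):
        r = dict(base, subject_id=f"s{i}")
        rows.append(r)
    rows[2]["gender"] = None            # missing covariate
    rows[5]["age"] = np.nan             # missing covariate
    rows[7]["score_memory"] = np.nan    # four domains only
    rows[8]["subject_id"] = "s0"        # duplicate
    return pd.DataFrame(rows)
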