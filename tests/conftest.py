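import numpy as np
import pandas as pd
import pytest

import saeprev as sp


@pytest.fixture(scope="session")
def small_geo():
    """25-tract grid county, 5 zips, 4 HRAs."""
    return sp.generate_geography(25, 5, 4, seed=3)


@pytest.fixture(scope="session")
def small_truth(small_geo):
    return sp.simulate_truth(small_geo, seed=11)


@pytest.fixture(scope="session")
def small_survey(small_geo, small_truth):
    return sp.simulate_survey(small_truth, small_geo, 4000, seed=12)


@pytest.fixture(scope="session")
def neutral_config():
    """Single-cell demography: equal selection, no outcome effect."""
    return sp.SurveyConfig(
        margins=[sp.DemographicMargin("cell", ["all"], [1.0], [1.0], [0.0])]
    )


def make_directs(theta, var_theta, degenerate=None, area_ids=None):
    """Hand-assembled direct-estimate table for smoothing-model tests."""
    theta = np.asarray(theta, float)
    k = len(theta)
    degenerate = np.zeros(k, bool) if degenerate is None else np.asarray(degenerate, bool)
    from scipy.special import expit

    return pd.DataFrame(
        {
            "area_id": area_ids if area_ids is not None else [f"a{i}" for i in range(k)],
            "n": 50,
            "p_hat": expit(theta),
            "var_p": np.nan,
            "theta_hat": np.where(degenerate, np.nan, theta),
            "var_theta": np.where(degenerate, np.nan, np.asarray(var_theta, float)),
            "degenerate": degenerate,
        }
    )
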