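import pandas as pd
import pytest

from ceatrial import TrialScenario, generate_trial
from ceatrial.config import (default_intervention_spec, default_limits,
                             default_unit_costs)


@pytest.fixture(scope="session")
def unit_costs():
    return default_unit_costs()


@pytest.fixture(scope="session")
def limits():
    return default_limits()


@pytest.fixture(scope="session")
def intervention_spec():
    return default_intervention_spec()


def clean_scenario(**overrides) -> TrialScenario:
    """Small trial without contamination/dropout/cost-nonresponse, with
    baselines far from the zero floor so latent changes are never clipped."""
    params = dict(
        n_clusters_per_arm=10, cluster_size_mean=20,
        contamination_rate=0.0, dropout_rate=0.0,
        cost_nonresponse_t0=0.0, cost_nonresponse_t1=0.0,
        weekly_t0_zero_prob=0.0, weekly_t0_mean=40.0, weekly_t0_sigma=0.2,
        binge_t0_zero_prob=0.0, binge_t0_mean=15.0, binge_t0_dispersion=20.0,
        sd_change_weekly=2.0, sd_change_binge=1.0,
        seed=0,
    )
    params.update(overrides)
    return TrialScenario(**params)


@pytest.fixture(scope="session")
def small_trial():
    df, truth = generate_trial(clean_scenario(seed=11))
    return df, truth


@pytest.fixture(scope="session")
def messy_trial(limits):
    """Study-like conditions at reduced size: contamination, nonresponse,
    heavy MNAR dropout."""
    sc = TrialScenario(n_clusters_per_arm=8, cluster_size_mean=40, seed=7)
    df, truth = generate_trial(sc, limits)
    return df, truth


@pytest.fixture()
def toy_costs():
    """Minimal cost table for outlier-exclusion tests."""
    return pd.DataFrame({
        "participant_id": ["a", "b", "c", "d"],
        "arm": ["control", "control", "intervention", "intervention"],
        "cost_societal_perspective": [4999.0, 5000.0, 5000.01, 7000.0],
        "cost_healthcare_perspective": [10.0, 20.0, 30.0, 6000.0],
    })
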