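import numpy as np
import pandas as pd
import pytest

import emtsig as es


@pytest.fixture(scope="session")
def diagnostic_fixture():
    return es.load_diagnostic_fixture()


@pytest.fixture(scope="session")
def prognostic_fixture():
    return es.load_prognostic_fixture()


def make_survival_cohort(
    n=60, beta=0.0, seed=0, endpoint="OS", censor_rate=0.2, gene="g"
):
    """One-gene proportional-hazards cohort for survival tests."""
    rng = np.random.default_rng(seed)
    expr = pd.DataFrame({gene: rng.normal(size=n)})
    params = es.SurvivalSimParams(
        n_patients=n,
        baseline_hazard=0.1,
        log_hr_per_sd={gene: beta} if beta else {},
        censor_rate=censor_rate,
        max_follow_up=40.0,
        endpoint=endpoint,
        rng_seed=seed + 1,
    )
    return es.simulate_survival_cohort(params, expr)


@pytest.fixture
def small_config():
    """Config suitable for small toy cohorts."""
    return es.AnalysisConfig(min_group_size=2, rng_seed=0)
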