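import numpy as np
import pytest

from icuq import CohortConfig
from icuq.prep import aggregate_baseline, clean_stay, filter_first_day, impute_mean
from icuq.quantiles import QUANTILE_FEATURES, assemble_feature_table, engineer_table
from icuq.synth import VITALS, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120-stay cohort with the default injected severity/tail signal."""
    return generate_cohort(CohortConfig(n_stays=120, seed=3))


@pytest.fixture(scope="session")
def prepared_cohort(small_cohort):
    stays = filter_first_day(small_cohort)
    return [clean_stay(s) for s in stays]


@pytest.fixture(scope="session")
def baseline_table(prepared_cohort):
    table = aggregate_baseline(prepared_cohort)
    return impute_mean(table, [f"{v}_mean" for v in VITALS])


@pytest.fixture(scope="session")
def quantile_table(prepared_cohort):
    table = engineer_table(prepared_cohort)
    return impute_mean(table, list(QUANTILE_FEATURES))


@pytest.fixture(scope="session")
def feature_tables(baseline_table, quantile_table):
    return {
        "baseline": assemble_feature_table(baseline_table, None, "baseline"),
        "quantiles": assemble_feature_table(baseline_table, quantile_table, "quantiles"),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
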