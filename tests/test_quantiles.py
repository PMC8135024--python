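"""The tail-quantile feature transform, checked stage by stage against
independent oracles (bisection on a numerically integrated normal CDF, the
closed-form truncated-normal second moment, and brute-force composition)."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from icuq.quantiles import (
    QUANTILE_FEATURES,
    NormalFit,
    QuantileConfig,
    assemble_feature_table,
    engineer_stay,
    extract_tails,
    fit_normal,
    modified_stats,
    quantile_percentage,
    tail_cutoffs,
)
from icuq.prep import BASELINE_PREDICTORS, aggregate_baseline
from icuq.synth import VITALS, CohortConfig, generate_cohort


# ---------------------------------------------------------------------------
# independent oracles

def _phi(x):
    return math.exp(-0.5 * x * x) / math.sqrt(2 * math.pi)


def _std_normal_cdf_numeric(x):
    """CDF by numerical integration of the density (no erf, no library ppf)."""
    val, _ = quad(_phi, -12.0, x)
    return val


def _ppf_bisection(p, lo=-12.0, hi=12.0, tol=1e-7):
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _std_normal_cdf_numeric(mid) < p:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _tail_sd_closed_form(c):
    """SD of a standard normal conditional on |X| > c (mean is 0 by symmetry):
    E[X^2 | |X|>c] = 2(c*phi(c) + 1 - Phi(c)) / P(|X|>c)."""
    tail_p = 2 * (1 - _std_normal_cdf_numeric(c))
    second = 2 * (c * _phi(c) + (1 - _std_normal_cdf_numeric(c))) / tail_p
    return math.sqrt(second)


# ---------------------------------------------------------------------------


class TestFitNormal:
    def test_single_value(self):
        assert fit_normal([5.0]) == NormalFit(5.0, 0.0)

    def test_two_values(self):
        fit = fit_normal([1.0, 3.0])
        assert fit.mean == 2.0
        assert fit.sd == pytest.approx(math.sqrt(2.0))

    def test_reproduces_sample_moments(self, rng):
        x = rng.normal(98.92, 27.89, size=200)
        fit = fit_normal(x)
        assert fit.mean == pytest.approx(float(np.mean(x)), abs=1e-9)
        assert fit.sd == pytest.approx(float(np.std(x, ddof=1)), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_normal([])


class TestTailCutoffs:
    def test_standard_normal_quartile_vs_bisection_oracle(self):
        low, high = tail_cutoffs(NormalFit(0.0, 1.0))
        assert abs(low - _ppf_bisection(0.25)) < 1e-4
        assert abs(high - _ppf_bisection(0.75)) < 1e-4
        assert low == pytest.approx(-0.67449, abs=1e-4)

    def test_median_probability_is_mean(self):
        cfg = QuantileConfig(p_low=0.499999, p_high=0.500001)
        low, high = tail_cutoffs(NormalFit(0.0, 1.0), cfg)
        assert low == pytest.approx(0.0, abs=1e-4)
        assert high == pytest.approx(0.0, abs=1e-4)

    def test_degenerate_sd(self):
        assert tail_cutoffs(NormalFit(7.0, 0.0)) == (7.0, 7.0)

    def test_location_scale(self):
        low, high = tail_cutoffs(NormalFit(10.0, 2.0))
        z = _ppf_bisection(0.25)
        assert low == pytest.approx(10.0 + 2.0 * z, abs=1e-3)
        assert high == pytest.approx(10.0 - 2.0 * z, abs=1e-3)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            QuantileConfig(p_low=0.0)
        with pytest.raises(ValueError):
            QuantileConfig(p_low=0.8, p_high=0.2)


class TestExtractTails:
    def test_enumeration(self):
        np.testing.assert_array_equal(
            extract_tails([1, 2, 3, 4, 5], 2.0, 4.0), [1.0, 4.0, 5.0]
        )

    def test_all_interior_empty(self):
        assert extract_tails([3.0, 3.5], 2.0, 4.0).size == 0

    def test_collapsed_cutoffs_return_everything(self):
        vals = [1.0, 2.0, 3.0]
        np.testing.assert_array_equal(extract_tails(vals, 2.0, 2.0), vals)

    def test_order_preserved(self):
        np.testing.assert_array_equal(
            extract_tails([5.0, 1.0, 4.0], 2.0, 4.0), [5.0, 1.0, 4.0]
        )


class TestModifiedStats:
    def test_two_tail_values(self):
        mean, sd = modified_stats([1.0, 9.0], NormalFit(5.0, 1.0))
        assert mean == 5.0
        assert sd == pytest.approx(math.sqrt(32.0))

    def test_empty_falls_back(self):
        assert modified_stats([], NormalFit(70.0, 5.0)) == (70.0, 0.0)

    def test_single_value(self):
        with pytest.warns(UserWarning):
            assert modified_stats([3.0], NormalFit(0.0, 1.0)) == (3.0, 0.0)

    def test_tail_sd_matches_truncated_normal_closed_form(self):
        # Monte-Carlo tails of the standard normal beyond +-0.6745 vs the
        # closed-form conditional second moment.
        c = 0.6745
        rng = np.random.default_rng(7)
        x = rng.standard_normal(1_000_000)
        tails = extract_tails(x, -c, c)
        mean_mod, std_mod = modified_stats(tails, NormalFit(0.0, 1.0))
        assert mean_mod == pytest.approx(0.0, abs=0.01)
        assert std_mod == pytest.approx(_tail_sd_closed_form(c), abs=0.01)
        assert std_mod == pytest.approx(1.363, abs=0.01)


class TestQuantilePercentage:
    @pytest.mark.parametrize(
        "k,n,expected", [(13, 16, 0.8125), (0, 7, 0.0), (7, 7, 1.0)]
    )
    def test_values(self, k, n, expected):
        assert quantile_percentage(k, n) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            quantile_percentage(0, 0)


class TestEngineerStay:
    def _random_stay(self, seed):
        (stay,) = generate_cohort(CohortConfig(n_stays=1, seed=seed, missing_rate=0.0))
        return stay

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_stagewise_composition(self, seed):
        """engineer_stay equals the four stages composed by hand."""
        stay = self._random_stay(seed)
        row = engineer_stay(stay)
        cfg = QuantileConfig()
        for v in VITALS:
            obs = stay.series[v].observed_values()
            fit = fit_normal(obs)
            low, high = tail_cutoffs(fit, cfg)
            tails = extract_tails(obs, low, high)
            mean_mod, std_mod = modified_stats(tails, fit, cfg)
            per = quantile_percentage(tails.size, obs.size)
            from icuq.quantiles import QUANTILE_FEATURE_NAMES

            mc, sc, pc = QUANTILE_FEATURE_NAMES[v]
            assert row[mc] == pytest.approx(mean_mod, rel=1e-12)
            assert row[sc] == pytest.approx(std_mod, rel=1e-12)
            assert row[pc] == pytest.approx(per, rel=1e-12)

    def test_constant_series_degeneracy(self):
        stay = self._random_stay(0)
        n = len(stay.series["heartrate"])
        stay.series["heartrate"].values[:] = 72.0
        row = engineer_stay(stay)
        assert row["HeartRateQuantPer"] == 1.0
        assert row["HeartRate_mean_mod"] == pytest.approx(72.0)
        assert row["heartRate_std_mod"] == 0.0

    def test_empty_series_gives_missing_features(self):
        stay = self._random_stay(1)
        stay.series["glucose"].times = np.zeros(0)
        stay.series["glucose"].values = np.zeros(0)
        row = engineer_stay(stay)
        assert math.isnan(row["glucose_mean_mod"])
        assert math.isnan(row["GlucoseQuantPer"])


class TestStatisticalProperties:
    def test_quantile_percentage_converges_to_half_under_normality(self, rng):
        # p_low + (1 - p_high) = 0.5 for exactly normal samples
        n = 20_000
        x = rng.standard_normal(n)
        fit = fit_normal(x)
        low, high = tail_cutoffs(fit)
        per = quantile_percentage(extract_tails(x, low, high).size, n)
        se = math.sqrt(0.25 / n)
        assert abs(per - 0.5) < 3 * se

    def test_modified_mean_near_mean_for_symmetric_samples(self, rng):
        x = rng.standard_normal(50_000)
        fit = fit_normal(x)
        low, high = tail_cutoffs(fit)
        mean_mod, _ = modified_stats(extract_tails(x, low, high), fit)
        assert abs(mean_mod - fit.mean) < 0.02

    def test_modified_sd_exceeds_sample_sd_on_normal_batches(self, rng):
        wins = 0
        for _ in range(20):
            x = rng.standard_normal(500)
            fit = fit_normal(x)
            low, high = tail_cutoffs(fit)
            _, std_mod = modified_stats(extract_tails(x, low, high), fit)
            wins += std_mod >= fit.sd
        assert wins == 20  # tail-only SD inflates the spread


class TestAssemble:
    def test_baseline_mode_has_12_predictors(self, baseline_table):
        t = assemble_feature_table(baseline_table, None, "baseline")
        predictors = [c for c in t.columns
                      if c not in ("stay_id", "patient_id", "los_days", "mortality")]
        assert predictors == list(BASELINE_PREDICTORS)
        assert len(predictors) == 12

    def test_quantiles_mode_has_33_predictors(self, baseline_table, quantile_table):
        t = assemble_feature_table(baseline_table, quantile_table, "quantiles")
        predictors = [c for c in t.columns
                      if c not in ("stay_id", "patient_id", "los_days", "mortality")]
        assert len(predictors) == 33
        assert predictors == list(BASELINE_PREDICTORS) + list(QUANTILE_FEATURES)

    def test_empty_cohort_keeps_header(self, baseline_table, quantile_table):
        t = assemble_feature_table(
            baseline_table.iloc[:0], quantile_table.iloc[:0], "quantiles"
        )
        assert len(t) == 0
        assert len([c for c in t.columns if c not in
                    ("stay_id", "patient_id", "los_days", "mortality")]) == 33

    def test_id_mismatch_rejected(self, baseline_table, quantile_table):
        with pytest.raises(ValueError, match="mismatch"):
            assemble_feature_table(
                baseline_table, quantile_table.iloc[1:], "quantiles"
            )

    def test_quant_per_in_unit_interval(self, quantile_table):
        per_cols = [c for c in QUANTILE_FEATURES if c.endswith("QuantPer")]
        vals = quantile_table[per_cols].to_numpy()
        assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0
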