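"""The equity metric: benchmark, formula, design variance, Rubin's rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hemkit as hk
from hemkit.hem import deficit_contributions

from conftest import make_design_frame


def expanded_median(values, weights):
    """Oracle: unweighted lower median of the integer-weight expansion."""
    expanded = np.sort(np.repeat(values, weights))
    # smallest value at which the cumulative share reaches 1/2
    k = int(np.ceil(len(expanded) / 2))
    return float(expanded[k - 1])


def expanded_hem(values, weights, benchmark, params):
    """Oracle: unweighted HEM on the record set repeated weight-many times."""
    return hk.hem_point(np.repeat(values, weights), benchmark, params)


class TestWeightedMedian:
    def test_equal_weight_privileged_example(self):
        vals = [0.841, 0.931, 0.983, 0.983, 0.983]
        assert hk.weighted_median(vals) == 0.983

    def test_unequal_weights(self):
        assert hk.weighted_median([1.0, 3.0], weights=[1.0, 3.0]) == 3.0

    @given(
        st.lists(
            st.tuples(st.sampled_from([0.401, 0.707, 0.841, 0.931, 0.983]), st.integers(1, 6)),
            min_size=1,
            max_size=20,
        )
    )
    def test_matches_integer_weight_expansion(self, pairs):
        values = np.array([v for v, _ in pairs])
        weights = np.array([w for _, w in pairs])
        assert hk.weighted_median(values, weights) == expanded_median(values, weights)

    def test_p90_quantile_definition(self):
        # cumulative shares 0.1 ... 1.0: the 90th percentile is the 9th value
        assert hk.weighted_quantile(list(range(1, 11)), 0.9) == 9.0

    def test_empty_and_bad_weights_raise(self):
        with pytest.raises(hk.EstimationError):
            hk.weighted_median([])
        with pytest.raises(hk.EstimationError):
            hk.weighted_median([1.0], weights=[-1.0])


class TestBenchmark:
    def _priv_frame(self, priv_values, other_values=()):
        n_priv, n_other = len(priv_values), len(other_values)
        return make_design_frame(
            list(priv_values) + list(other_values),
            sex=["male"] * n_priv + ["female"] * n_other,
            race_ethnicity=["white_nl"] * (n_priv + n_other),
            income_imp1=["ge400"] * n_priv + ["lt150"] * n_other,
        )

    def test_privileged_median_mode(self):
        df = self._priv_frame([0.841, 0.931, 0.983, 0.983, 0.983], [0.401, 0.707])
        spec = hk.BenchmarkSpec(min_cell_size=1)
        assert hk.compute_benchmark(df, "general_health", spec) == 0.983

    def test_population_p90_mode(self):
        df = self._priv_frame(list(np.linspace(0.1, 1.0, 10)))
        spec = hk.BenchmarkSpec(mode="population_p90")
        assert hk.compute_benchmark(df, "general_health", spec) == pytest.approx(0.9)

    def test_degenerate_population_same_in_both_modes(self):
        df = self._priv_frame([0.9] * 60)
        for mode in ("privileged_median", "population_p90"):
            spec = hk.BenchmarkSpec(mode=mode, min_cell_size=1)
            assert hk.compute_benchmark(df, "general_health", spec) == 0.9

    def test_empty_privileged_group_raises(self):
        df = self._priv_frame([], [0.5, 0.6])
        with pytest.raises(hk.EstimationError):
            hk.compute_benchmark(df, "general_health", hk.BenchmarkSpec())

    def test_small_cell_warns(self):
        df = self._priv_frame([0.9] * 10)
        with pytest.warns(UserWarning, match="privileged cell"):
            hk.compute_benchmark(df, "general_health", hk.BenchmarkSpec(min_cell_size=50))

    def test_unknown_mode_rejected(self):
        with pytest.raises(hk.ConfigurationError):
            hk.BenchmarkSpec(mode="pooled_mean")


class TestHemFormula:
    def test_all_at_or_above_benchmark_gives_exactly_1000(self):
        assert hk.hem_point([0.9, 0.95, 1.2], benchmark=0.9) == 1000.0

    def test_single_worst_case_closed_form(self):
        expected = 1000.0 * (1.0 - 2.0**2.5)
        assert hk.hem_point([0.0], benchmark=1.0) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(-4656.854, abs=1e-3)

    def test_half_population_at_half_benchmark_gives_500(self):
        values = [1.0] * 50 + [0.5] * 50
        assert hk.hem_point(values, benchmark=1.0) == pytest.approx(500.0, abs=1e-9)

    def test_equal_weights_reduce_to_plain_mean(self):
        values = [0.3, 0.7, 1.0, 0.9]
        assert hk.hem_point(values, 0.9, weights=[2.0, 2.0, 2.0, 2.0]) == pytest.approx(
            hk.hem_point(values, 0.9)
        )

    def test_lowering_a_below_benchmark_value_strictly_decreases(self):
        base = hk.hem_point([0.5, 0.9], benchmark=0.9)
        worse = hk.hem_point([0.4, 0.9], benchmark=0.9)
        assert worse < base

    def test_raising_an_above_benchmark_value_changes_nothing(self):
        a = hk.hem_point([0.5, 0.95], benchmark=0.9)
        b = hk.hem_point([0.5, 5.0], benchmark=0.9)
        assert a == b

    def test_convexity_concentration_decreases_hem(self):
        # same total deficit, concentrated on one individual
        spread = hk.hem_point([0.8, 0.8, 1.0, 1.0], benchmark=1.0)
        packed = hk.hem_point([0.6, 1.0, 1.0, 1.0], benchmark=1.0)
        assert packed < spread

    @given(
        st.lists(
            st.tuples(st.floats(0.0, 2.0), st.integers(1, 5)), min_size=1, max_size=15
        ),
        st.floats(0.5, 1.5),
    )
    def test_weight_expansion_oracle_and_range(self, pairs, benchmark):
        values = np.array([v for v, _ in pairs])
        weights = np.array([w for _, w in pairs])
        params = hk.HEMParams()
        weighted = hk.hem_point(values, benchmark, params, weights)
        assert weighted == pytest.approx(expanded_hem(values, weights, benchmark, params), rel=1e-12)
        assert params.floor - 1e-9 <= weighted <= 1000.0 + 1e-9

    def test_nonpositive_benchmark_raises(self):
        with pytest.raises(hk.EstimationError):
            hk.hem_point([0.5], benchmark=0.0)

    def test_empty_population_raises(self):
        with pytest.raises(hk.EstimationError):
            hk.hem_point([], benchmark=1.0)

    def test_invalid_params_rejected(self):
        with pytest.raises(hk.ConfigurationError):
            hk.HEMParams(alpha=1.0)
        with pytest.raises(hk.ConfigurationError):
            hk.HEMParams(beta=0.0)


class TestDesignVariance:
    def test_identical_contributions_give_zero_se(self):
        df = make_design_frame([0.5] * 10)
        assert hk.estimate_variance(df, "general_health", 1.0) == 0.0

    def test_single_stratum_matches_closed_form_sample_mean_se(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(0.2, 1.0, size=40)
        df = make_design_frame(values)
        params = hk.HEMParams()
        c = deficit_contributions(values, 0.95, params)
        closed_form = params.rescale * c.std(ddof=1) / np.sqrt(len(c))
        se = hk.estimate_variance(df, "general_health", 0.95, params)
        assert se == pytest.approx(closed_form, abs=1e-10)

    def test_balanced_stratification_beats_srs_on_stratum_shift(self):
        # two strata whose values differ by a constant shift; stratified
        # between-PSU variance removes the between-stratum component
        rng = np.random.default_rng(8)
        base = rng.uniform(0.3, 0.6, size=30)
        values = np.concatenate([base, base + 0.3])
        df = make_design_frame(values)
        df["stratum"] = [0] * 30 + [1] * 30
        df["psu"] = list(range(30)) * 2
        stratified = hk.estimate_variance(df, "general_health", 1.0)
        df_srs = make_design_frame(values)  # one stratum, each record its own PSU
        srs = hk.estimate_variance(df_srs, "general_health", 1.0)
        assert stratified < srs

    def test_single_psu_stratum_errors_by_default(self):
        df = make_design_frame([0.5, 0.6, 0.7])
        df["stratum"] = [0, 1, 1]
        df["psu"] = [0, 0, 1]
        with pytest.raises(hk.EstimationError):
            hk.estimate_variance(df, "general_health", 1.0)
        se = hk.estimate_variance(df, "general_health", 1.0, single_psu="center")
        assert np.isfinite(se) and se > 0


class TestRubinCombining:
    def _estimate(self, value, se, year=2000, measure="general_health"):
        return hk.HEMEstimate(
            year=year, measure=measure, value=value, se=se,
            ci_low=value - 1.96 * se, ci_high=value + 1.96 * se, n=100, benchmark=0.983,
        )

    def test_identical_replicates_reproduce_single_imputation(self):
        est = self._estimate(990.0, 2.0)
        combined = hk.combine_imputations([est] * 5)
        assert combined.value == 990.0
        assert combined.se == pytest.approx(2.0)

    def test_hand_computed_two_imputation_case(self):
        a, b = self._estimate(990.0, 1.0), self._estimate(994.0, 1.0)
        combined = hk.combine_imputations([a, b])
        assert combined.value == pytest.approx(992.0)
        # between-variance 8, total variance 1 + 1.5 * 8 = 13
        assert combined.se**2 == pytest.approx(13.0)

    def test_single_estimate_passthrough(self):
        est = self._estimate(985.0, 3.0)
        assert hk.combine_imputations([est]) is est

    def test_mismatched_year_or_measure_raises(self):
        with pytest.raises(hk.CombinationError):
            hk.combine_imputations([self._estimate(990, 1), self._estimate(990, 1, year=2001)])
        with pytest.raises(hk.CombinationError):
            hk.combine_imputations(
                [self._estimate(990, 1), self._estimate(990, 1, measure="sdq")]
            )
        with pytest.raises(hk.CombinationError):
            hk.combine_imputations([])


class TestHemOnMicrodata:
    def test_estimate_invariants_on_synthetic_years(self, small_coded):
        params = hk.HEMParams()
        for measure in ("general_health", "school_days"):
            for est in hk.hem_series(small_coded, measure):
                assert est.value <= 1000.0
                assert est.value >= params.floor
                assert est.ci_low <= est.value <= est.ci_high
                assert est.n > 0 and est.se >= 0

    def test_pooled_benchmark_option(self, small_coded):
        pooled = hk.hem_series(
            small_coded, "general_health", hk.BenchmarkSpec(per_year=False)
        )
        assert len({e.benchmark for e in pooled}) == 1

    def test_scenario_ordering_joint_with_disparity(self):
        """Equity falls across the illustration scenarios while the gap holds at 20."""
        hems, gaps = [], []
        for sid in (1, 2, 3, 4):
            spec = hk.ScenarioSpec(
                scenario_id=sid, n_privileged=30_000, n_nonprivileged=30_000, seed=100 + sid
            )
            p, n = hk.generate_scenario(spec)
            bench = hk.weighted_median(p)
            hems.append(hk.hem_point(np.concatenate([p, n]), bench))
            gaps.append(hk.scenario_gap(p, n))
        assert hems[0] > hems[1] > hems[2]
        assert hems[3] < hems[0]
        assert np.allclose(gaps, 20.0, atol=0.4)
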