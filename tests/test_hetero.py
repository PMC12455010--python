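import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kvinact import (
    DomainError,
    UnknownConditionError,
    ValidationError,
    boxplot_stats,
    compare_conditions,
    pearson_corr,
    whisker_span,
)


def brute_force_reference(values, convention="linear"):
    """Independent Tukey-boxplot oracle: explicit quantile formula plus
    per-point exhaustive outlier classification."""
    xs = sorted(values)
    n = len(xs)

    def quantile(p):
        h = (n - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, n - 1)
        return xs[lo] + (h - lo) * (xs[hi] - xs[lo])

    if convention == "linear":
        q1, q3 = quantile(0.25), quantile(0.75)
    else:  # Tukey hinges
        h = (n + 1) // 2
        lower, upper = xs[:h], xs[-h:]
        q1 = (lower[(len(lower) - 1) // 2] + lower[len(lower) // 2]) / 2
        q3 = (upper[(len(upper) - 1) // 2] + upper[len(upper) // 2]) / 2
    iqr = q3 - q1
    outliers = [x for x in xs if x < q1 - 1.5 * iqr or x > q3 + 1.5 * iqr]
    inside = [x for x in xs if x not in outliers]
    return q1, q3, min(inside), max(inside), outliers


class TestBoxplotStats:
    def test_symmetric_small_set(self):
        st_ = boxplot_stats([1, 2, 3, 4, 5])
        assert st_.median == 3 and st_.whisker_low == 1 and st_.whisker_high == 5
        assert st_.outliers == ()

    def test_single_far_outlier_flagged(self):
        # type-7 quartiles of {1,2,3,4,100}: q1=2, q3=4, fence 4+1.5*2=7 < 100
        st_ = boxplot_stats([1, 2, 3, 4, 100])
        assert st_.outliers == (100.0,)
        assert st_.whisker_high == 4.0

    def test_degenerate_all_equal(self):
        st_ = boxplot_stats([7.0] * 6)
        assert st_.median == st_.q1 == st_.q3 == 7.0
        assert st_.iqr == 0.0 and st_.whisker_span == 0.0 and st_.outliers == ()

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            boxplot_stats([])

    def test_low_n_flagged_but_computed(self):
        st_ = boxplot_stats([1.0, 2.0])
        assert st_.low_n and st_.n == 2

    @pytest.mark.parametrize("convention", ["linear", "hinges"])
    def test_matches_brute_force_on_all_small_subsets(self, convention):
        # exhaustive check over every subset of size <= 8 of a fixed
        # 12-value pool, including ties and a gross outlier
        pool = [3.1, 7.7, 7.7, 12.0, 15.5, 18.2, 21.0, 26.4, 31.9, 44.0, 95.0, 260.0]
        for size in range(1, 9):
            for subset in itertools.combinations(pool, size):
                got = boxplot_stats(subset, convention=convention)
                q1, q3, wlo, whi, outliers = brute_force_reference(subset, convention)
                assert got.q1 == pytest.approx(q1), subset
                assert got.q3 == pytest.approx(q3), subset
                assert got.whisker_low == pytest.approx(wlo), subset
                assert got.whisker_high == pytest.approx(whi), subset
                assert list(got.outliers) == pytest.approx(outliers), subset

    @given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=40),
           st.floats(-100.0, 100.0), st.floats(0.1, 10.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_invariants_and_affine_equivariance(self, values, shift, scale):
        st_ = boxplot_stats(values)
        assert st_.q1 <= st_.median <= st_.q3
        assert st_.iqr == pytest.approx(st_.q3 - st_.q1)
        # whiskers are observations, so they bracket the median; they may
        # land inside the box when interpolated quartiles fall in data gaps
        assert st_.whisker_low <= st_.median <= st_.whisker_high
        assert st_.n == len(st_.outliers) + sum(
            st_.whisker_low <= v <= st_.whisker_high for v in values
        )
        moved = boxplot_stats([scale * v + shift for v in values])
        assert moved.whisker_span == pytest.approx(scale * st_.whisker_span, rel=1e-9, abs=1e-6)

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValidationError):
            boxplot_stats([1, 2, 3], convention="excel")


class TestWhiskerSpan:
    def test_span_is_whisker_distance(self):
        st_ = boxplot_stats([1, 2, 3, 4, 5])
        assert whisker_span(st_) == 4.0

    def test_scaling_data_scales_span(self):
        a = whisker_span(boxplot_stats([1, 2, 3, 4, 5]))
        b = whisker_span(boxplot_stats([2, 4, 6, 8, 10]))
        assert b == pytest.approx(2 * a)


class TestPearson:
    def test_perfect_linear(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert pearson_corr(x, [2 * v + 1 for v in x]) == pytest.approx(1.0)
        assert pearson_corr(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            pearson_corr([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_length_and_size_validation(self):
        with pytest.raises(ValidationError):
            pearson_corr([1, 2], [3, 4])
        with pytest.raises(ValidationError):
            pearson_corr([1, 2, 3], [3, 4])

    def test_null_correlation_between_independent_width_and_amplitude(self):
        # peak current (conductance draw) and inactivation delay are generated
        # independently in the simulator, so across seeded replicate cohorts
        # |r| should stay below the ~2/sqrt(n) null band in >= 95% of runs
        from kvinact import ConditionSpec, NoiseModel, make_protocol, measure_cohort, simulate_cohort
        from kvinact.synth import delay_spread_sampler

        proto = make_protocol(step_potentials=[80.0])
        noise = NoiseModel(baseline_sd=0.0, leak_conductance=0.0)
        n = 30
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            spec = ConditionSpec("null", delay_spread_sampler(120.0, 60.0), n)
            cells = simulate_cohort([spec], protocol=proto, noise=noise, seed=seed * 37)
            table, _ = measure_cohort(cells)
            r = pearson_corr(table["i_max_nA"], table["inac_width_ms"])
            hits += abs(r) < 2.0 / np.sqrt(n)
        assert hits / n_rep >= 0.95


def make_measurements(widths_by_condition, i_max=2.0):
    rows = []
    rng = np.random.default_rng(0)
    for cond, widths in widths_by_condition.items():
        for i, w in enumerate(widths):
            rows.append({
                "cell_id": f"{cond}-{i}", "condition": cond, "i_max_nA": i_max + rng.uniform(0, 1),
                "inac_width_ms": float(w), "censored": False,
            })
    return pd.DataFrame(rows)


class TestCompareConditions:
    def test_identical_groups_have_ratio_one(self):
        widths = [10.0, 20.0, 30.0, 40.0]
        report = compare_conditions(
            make_measurements({"control": widths, "treated": widths}), "control"
        )
        assert report.span_ratio["treated"] == pytest.approx(1.0)
        assert report.conditions["treated"].n == 4

    def test_unknown_reference_rejected(self):
        with pytest.raises(UnknownConditionError):
            compare_conditions(make_measurements({"control": [1, 2, 3]}), "nonexistent")

    def test_censored_widths_excluded_in_sensitivity_mode(self):
        df = make_measurements({"control": [10.0, 20.0, 30.0, 499.0]})
        df.loc[df["inac_width_ms"] == 499.0, "censored"] = True
        keep = compare_conditions(df, "control", include_censored=True)
        drop = compare_conditions(df, "control", include_censored=False)
        assert keep.conditions["control"].n == 4
        assert drop.conditions["control"].n == 3
        assert keep.n_censored["control"] == 1

    def test_counts_conserved_per_condition(self):
        df = make_measurements({"control": range(10, 40), "treated": range(5, 15)})
        report = compare_conditions(df, "control")
        assert report.conditions["control"].n == 30
        assert report.conditions["treated"].n == 10
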