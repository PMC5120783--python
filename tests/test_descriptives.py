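import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_manual_dataset
from esmstaging.descriptives import (
    GroupingError,
    assign_quartile_groups,
    boxplot_summaries,
    correlation_table,
    floor_profile,
    grouping_from_cutpoints,
    search_equal_variance_cutpoints,
    subgroup_table,
    summarize,
)
from esmstaging.synthetic_esm import EsmDataset


def brute_force_skewness(x):
    """Adjusted Fisher-Pearson standardized third moment, from scratch."""
    x = np.asarray(x, dtype=float)
    n = x.size
    m = x.mean()
    s = np.sqrt(np.sum((x - m) ** 2) / (n - 1))
    g1 = np.sum((x - m) ** 3) / n / (np.sum((x - m) ** 2) / n) ** 1.5
    return g1 * np.sqrt(n * (n - 1)) / (n - 2)


class TestSummarize:
    def test_degenerate_all_at_floor(self):
        s = summarize([1.0] * 10, 1, 7)
        assert s.variance == 0
        assert s.floor_pct == 100 and s.ceiling_pct == 0

    def test_symmetric_scores_have_zero_skew(self):
        s = summarize([1, 2, 3, 4, 5, 6, 7], 1, 7)
        assert s.skewness == pytest.approx(0, abs=1e-12)

    def test_floor_ceiling_counting(self):
        s = summarize([1, 1, 1, 7], 1, 7)
        assert s.floor_pct == pytest.approx(75)
        assert s.ceiling_pct == pytest.approx(25)

    def test_small_samples_report_skew_as_missing(self):
        assert np.isnan(summarize([1, 2], 1, 7).skewness)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize([], 1, 7)

    @given(st.lists(st.floats(1, 7), min_size=4, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_third_moment(self, scores):
        if np.ptp(scores) == 0:
            return
        s = summarize(scores, 1, 7)
        assert s.skewness == pytest.approx(brute_force_skewness(scores), rel=1e-9)
        assert s.variance == pytest.approx(np.var(scores, ddof=1), rel=1e-9)


class TestQuartileGrouping:
    def test_distinct_scores_split_evenly(self):
        sev = pd.Series(np.arange(1.0, 9.0), index=range(1, 9))
        g = assign_quartile_groups(sev)
        assert g.group_sizes == (2, 2, 2, 2)

    def test_all_tied_scores_fail(self):
        with pytest.raises(GroupingError):
            assign_quartile_groups(pd.Series([2.0] * 8))

    def test_duplicated_pairs_follow_percentile_rule(self):
        sev = pd.Series([1, 1, 2, 2, 3, 3, 4, 4], index=range(8), dtype=float)
        g = assign_quartile_groups(sev)
        got = [sorted(sev[g.group_of_person == k]) for k in range(1, 5)]
        assert got == [[1, 1], [2, 2], [3, 3], [4, 4]]

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        sev = pd.Series(rng.gamma(2, 1, size=40))
        a = assign_quartile_groups(sev)
        b = assign_quartile_groups(np.exp(sev))  # strictly increasing map
        assert (a.group_of_person == b.group_of_person).all()

    def test_cutpoint_upper_boundary_inclusive(self):
        sev = pd.Series([1.0, 2.0, 3.0, 4.0], index=[1, 2, 3, 4])
        g = grouping_from_cutpoints(sev, [1.0, 2.0, 3.0])
        assert g.group_of_person.tolist() == [1, 2, 3, 4]


class TestCorrelationTable:
    def test_self_correlation_is_one(self, default_dataset):
        ct = correlation_table(default_dataset)
        assert np.allclose(np.diag(ct.pearson), 1.0)
        assert np.allclose(np.diag(ct.spearman), 1.0)

    def test_monotone_nonlinear_relation(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        rows = [[1, 1, 1 + i // 10, 1 + i % 10, 1.0, 1.0, 1.0, 1.0] for i in range(500)]
        ds = make_manual_dataset(rows)
        ds.frame["na"] = x
        ds.frame["pa"] = np.exp(x)
        ds.frame["day"] = np.arange(500) // 10 + 1
        ds.frame["beep"] = np.arange(500) % 10 + 1
        ct = correlation_table(ds)
        assert ct.spearman.loc["na", "pa"] == pytest.approx(1.0)
        assert ct.pearson.loc["na", "pa"] < 1.0

    def test_constant_variable_reported_undefined(self):
        rows = [[1, 1, 1, b + 1, 1.0 + b / 10, 4.0 - b / 10, 1.0, 2.0] for b in range(10)]
        ds = make_manual_dataset(rows)
        ct = correlation_table(ds)
        assert np.isnan(ct.pearson.loc["par", "na"])

    def test_spearman_equals_pearson_on_ranks(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 300))  # continuous: tie-free
        rows = [[1, 1, 1 + i // 10, 1 + i % 10, 1.0, 1.0, 1.0, 1.0] for i in range(300)]
        ds = make_manual_dataset(rows)
        ds.frame["na"], ds.frame["pa"] = x, y
        ds.frame["day"] = np.arange(300) // 10 + 1
        ds.frame["beep"] = np.arange(300) % 10 + 1
        ct = correlation_table(ds)
        rx = pd.Series(x).rank()
        ry = pd.Series(y).rank()
        assert ct.spearman.loc["na", "pa"] == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_default_generator_sign_pattern(self, default_dataset):
        """PA anti-correlates with severity and the negative states;
        NA and PAR correlate positively."""
        ct = correlation_table(default_dataset)
        for tab in (ct.pearson, ct.spearman):
            assert tab.loc["pa", "scl"] < 0
            assert tab.loc["pa", "na"] < 0
            assert tab.loc["pa", "par"] < 0
            assert tab.loc["na", "par"] > 0
            assert tab.loc["na", "scl"] > 0


class TestEqualVarianceSearch:
    def test_homoscedastic_state_achieves_tolerance(self):
        rng = np.random.default_rng(3)
        rows = []
        for p in range(60):
            scl = rng.uniform(1, 5)
            for b in range(10):
                rows.append([p, p, 1 + b // 10, 1 + b % 10,
                             np.clip(4 + rng.standard_normal(), 1, 7),
                             4.0, 1.0, scl])
        ds = make_manual_dataset(rows)
        res = search_equal_variance_cutpoints(ds, "na", tolerance=1.5,
                                              min_group_persons=5)
        assert res.achieved
        assert res.variance_ratio < 1.5

    def test_default_skewed_data_cannot_equalize(self, default_dataset):
        """Mirrors the failed attempts to balance subgroup variances of a
        floor-inflated state by moving severity cutpoints."""
        res = search_equal_variance_cutpoints(default_dataset, "na", tolerance=1.5)
        assert not res.achieved
        assert res.variance_ratio > 1.5

    def test_too_few_distinct_severities(self):
        rows = [[p, p, 1, b + 1, 1.0, 4.0, 1.0, float(p % 2)] for p in range(10)
                for b in range(5)]
        ds = make_manual_dataset(rows)
        with pytest.raises(GroupingError):
            search_equal_variance_cutpoints(ds, "na")

    def test_ratio_at_least_one(self, small_dataset):
        res = search_equal_variance_cutpoints(
            small_dataset, "na", min_group_persons=5
        )
        assert res.variance_ratio >= 1.0


class TestFloorProfile:
    def test_counts_partition_nonmissing(self, default_dataset):
        prof = floor_profile(default_dataset, "na", bin_width=0.2)
        assert prof["n_measurements"].sum() == default_dataset.frame["na"].notna().sum()

    def test_all_floor(self):
        rows = [[1, 1, 1, b + 1, 1.0, 4.0, 1.0, 1.5] for b in range(10)]
        prof = floor_profile(make_manual_dataset(rows), "na")
        nonempty = prof[prof.n_measurements > 0]
        assert (nonempty["floor_prop"] == 1.0).all()

    def test_no_floor(self):
        rows = [[1, 1, 1, b + 1, 2.0, 4.0, 2.0, 1.5] for b in range(10)]
        prof = floor_profile(make_manual_dataset(rows), "na")
        nonempty = prof[prof.n_measurements > 0]
        assert (nonempty["floor_prop"] == 0.0).all()

    def test_bad_bin_width(self, small_dataset):
        with pytest.raises(ValueError):
            floor_profile(small_dataset, "na", bin_width=0)


class TestSubgroupTable:
    def test_structure_and_variance_gradient(self, default_dataset, default_grouping):
        table = subgroup_table(default_dataset, default_grouping)
        blocks = table.index.get_level_values("block").unique()
        assert set(blocks) == {"total", "severity_1", "severity_2", "severity_3", "severity_4"}
        na_var = [table.loc[(f"severity_{g}", "variance"), "na"] for g in range(1, 5)]
        assert all(a < b for a, b in zip(na_var, na_var[1:]))

    def test_boxplot_whiskers_respect_iqr_rule(self, default_dataset, default_grouping):
        box = boxplot_summaries(default_dataset, "pa", default_grouping)
        assert len(box) == 4
        assert (box["q1"] <= box["median"]).all()
        assert (box["median"] <= box["q3"]).all()
        iqr = box["q3"] - box["q1"]
        assert (box["lower_whisker"] >= box["q1"] - 1.5 * iqr - 1e-12).all()
        assert (box["upper_whisker"] <= box["q3"] + 1.5 * iqr + 1e-12).all()
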