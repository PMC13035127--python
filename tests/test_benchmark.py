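import math

import numpy as np
import pandas as pd
import pytest

from patmetrics import (
    PatRecord,
    RegionSpec,
    assemble_features,
    compare_metric_runs,
    compute_metric_table,
    dmr_differential_score,
    filter_missing,
    nested_cv_classify,
    pooled_roc,
    quadrant_partition,
    rank_top_k,
    top_k_intersection,
)


def make_table(values: np.ndarray, metric: str = "mpci") -> pd.DataFrame:
    rows = []
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            rows.append((f"s{i}", f"r{j}", metric, values[i, j]))
    return pd.DataFrame(rows, columns=["sample", "region", "metric", "value"])


class TestComputeMetricTable:
    def test_long_format_and_missing(self):
        region = RegionSpec("chr1", 1, 4)
        empty_region = RegionSpec("chr1", 50, 53)
        samples = {"a": [PatRecord("chr1", 1, "CCCC", 5)]}
        table = compute_metric_table(samples, [region, empty_region], ["mpci", "mhl"])
        assert len(table) == 4
        got = table.set_index(["region", "metric"])["value"]
        assert got[(region.name, "mpci")] == 1.0
        assert math.isnan(got[(empty_region.name, "mhl")])

    def test_unknown_metric_errors(self):
        with pytest.raises(ValueError, match="unknown"):
            compute_metric_table({}, [], ["bogus"])


class TestAssembleFeatures:
    def test_pivot_shape(self):
        table = make_table(np.arange(12.0).reshape(3, 4))
        X = assemble_features(table, "mpci")
        assert X.shape == (3, 4)
        assert X.loc["s1", "r2"] == 6.0

    def test_empty_region_list_errors(self):
        table = make_table(np.ones((2, 2)))
        with pytest.raises(ValueError, match="empty region"):
            assemble_features(table, "mpci", regions=[])

    def test_duplicate_rows_error(self):
        table = make_table(np.ones((2, 2)))
        dup = pd.concat([table, table.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            assemble_features(dup, "mpci")

    def test_unknown_metric_errors(self):
        with pytest.raises(ValueError, match="not present"):
            assemble_features(make_table(np.ones((2, 2))), "mhl")


class TestFilterMissing:
    def test_complete_unchanged(self):
        X = pd.DataFrame(np.ones((10, 5)))
        assert filter_missing(X).equals(X)

    def test_feature_over_10pct_dropped(self):
        X = pd.DataFrame(np.ones((100, 3)))
        X.iloc[:11, 0] = np.nan  # 11% missing -> dropped
        X.iloc[:10, 1] = np.nan  # exactly 10% -> kept
        out = filter_missing(X)
        assert list(out.columns) == [1, 2]

    def test_sample_over_80pct_dropped(self):
        X = pd.DataFrame(np.ones((5, 100)))
        X.iloc[0, :81] = np.nan
        out = filter_missing(X, max_feature_missing=1.0)
        assert list(out.index) == [1, 2, 3, 4]

    def test_median_imputation(self):
        X = pd.DataFrame(
            {"f": [1.0, 3.0, np.nan] + [2.0] * 27, "g": np.ones(30)}
        )
        out = filter_missing(X)
        assert out["f"].iloc[2] == 2.0
        assert not filter_missing(X, impute=False)["f"].notna().all()

    def test_everything_filtered_errors(self):
        X = pd.DataFrame(np.full((4, 3), np.nan))
        with pytest.raises(ValueError):
            filter_missing(X)


class TestNestedCv:
    def _separable(self, seed=0, n=40, p=6):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(-3, 0.3, (n // 2, p)), rng.normal(3, 0.3, (n // 2, p))])
        y = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        return X, y

    def test_separable_pooled_auc_one(self):
        X, y = self._separable()
        report = nested_cv_classify(X, y, seed=1)
        assert report.pooled_auc == 1.0
        assert all(a == 1.0 for a in report.fold_auc)

    def test_seed_determinism(self):
        X, y = self._separable(seed=3)
        a = nested_cv_classify(X, y, seed=7)
        b = nested_cv_classify(X, y, seed=7)
        assert a.summary() == b.summary()
        assert np.array_equal(a.pooled_scores, b.pooled_scores)

    def test_single_class_errors(self):
        X = np.ones((10, 3))
        with pytest.raises(ValueError, match="classes"):
            nested_cv_classify(X, np.zeros(10))

    def test_rates_in_unit_interval(self):
        X, y = self._separable(seed=5)
        rng = np.random.default_rng(0)
        report = nested_cv_classify(X, rng.permutation(y), seed=2)
        for vals in (report.fold_auc, report.fold_accuracy, report.fold_sensitivity, report.fold_specificity):
            assert all(0.0 <= v <= 1.0 for v in vals if not math.isnan(v))


class TestPooledRoc:
    def test_perfect_scores(self):
        _, _, auc = pooled_roc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_constant_scores_half(self):
        _, _, auc = pooled_roc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_four_score_example(self):
        # positives {0.9, 0.4}, negatives {0.6, 0.1}: 3 of 4 pairs ranked right
        _, _, auc = pooled_roc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert auc == 0.75

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            pooled_roc([1, 1], [0.5, 0.6])

    def test_matches_rank_statistic(self, rng):
        # trapezoid ROC area equals the Mann-Whitney rank statistic
        from scipy.stats import mannwhitneyu

        labels = rng.integers(0, 2, 60)
        labels[:2] = [0, 1]
        scores = rng.random(60)
        _, _, auc = pooled_roc(labels, scores)
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert auc == pytest.approx(u / ((labels == 1).sum() * (labels == 0).sum()))

    def test_roc_points_monotone(self, rng):
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        fpr, tpr, _ = pooled_roc(labels, rng.random(40))
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)


class TestCompareMetricRuns:
    def test_identical_runs_not_significant(self):
        a = {"auc": [0.9, 0.8, 0.85, 0.9, 0.88]}
        out = compare_metric_runs(a, a, paired=True)
        assert out["p_raw"].iloc[0] == 1.0
        assert not out["significant"].iloc[0]

    def test_bh_worked_example(self):
        from patmetrics import bh_adjust

        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_exact_rank_sum_disjoint(self):
        a = {"auc": [1, 2, 3, 4, 5]}
        b = {"auc": [6, 7, 8, 9, 10]}
        out = compare_metric_runs(a, b, paired=False)
        assert out["p_raw"].iloc[0] == pytest.approx(2 / 252)

    def test_bh_monotone_and_geq_raw(self):
        rng = np.random.default_rng(4)
        a = {f"m{i}": rng.random(6).tolist() for i in range(5)}
        b = {f"m{i}": (rng.random(6) + 0.1).tolist() for i in range(5)}
        out = compare_metric_runs(a, b, paired=False)
        assert (out["p_adjusted"] >= out["p_raw"] - 1e-12).all()
        s = out.sort_values("p_raw")
        assert s["p_adjusted"].is_monotonic_increasing

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            compare_metric_runs({"auc": [1.0]}, {"auc": [2.0]})


class TestDmrScoring:
    def test_identical_groups_zero(self):
        table = make_table(np.ones((4, 3)))
        s = dmr_differential_score(table, "mpci", ["s0", "s1"], ["s2", "s3"])
        assert (s == 0).all()

    def test_mpci_scale_difference(self):
        vals = np.vstack([np.full((2, 3), 1.0), np.full((2, 3), -1.0)])
        table = make_table(vals)
        s = dmr_differential_score(table, "mpci", ["s0", "s1"], ["s2", "s3"])
        assert (s == 2.0).all()

    def test_mhl_doubling(self):
        vals = np.vstack([np.full((2, 3), 1.0), np.full((2, 3), 0.0)])
        table = make_table(vals, metric="mhl")
        s = dmr_differential_score(table, "mhl", ["s0", "s1"], ["s2", "s3"], scale_factor=2.0)
        assert (s == 2.0).all()

    def test_antisymmetric_in_group_order(self, rng):
        table = make_table(rng.random((6, 5)))
        a = dmr_differential_score(table, "mpci", ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        b = dmr_differential_score(table, "mpci", ["s3", "s4", "s5"], ["s0", "s1", "s2"])
        assert np.allclose(a, -b)

    def test_missing_group_scores_nan(self):
        vals = np.ones((4, 2))
        vals[0, 0] = np.nan
        vals[1, 0] = np.nan
        table = make_table(vals)
        s = dmr_differential_score(table, "mpci", ["s0", "s1"], ["s2", "s3"])
        assert math.isnan(s["r0"]) and s["r1"] == 0.0


class TestRanking:
    def test_full_ordering(self):
        s = pd.Series([0.1, 0.9, 0.5], index=["a", "b", "c"])
        assert rank_top_k(s, 3) == ["b", "c", "a"]

    def test_identical_vectors_full_intersection(self):
        s = pd.Series(np.arange(20.0), index=[f"r{i}" for i in range(20)])
        assert top_k_intersection(rank_top_k(s, 10), rank_top_k(s.copy(), 10)) == 10

    def test_reversed_vectors_zero_intersection(self):
        idx = [f"r{i}" for i in range(100)]
        s = pd.Series(np.arange(100.0), index=idx)
        assert top_k_intersection(rank_top_k(s, 10), rank_top_k(-s, 10)) == 0

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            rank_top_k(pd.Series([1.0]), 2)


class TestQuadrants:
    def test_four_centers(self):
        a = pd.Series([1, 1, -1, -1], index=list("wxyz"), dtype=float)
        b = pd.Series([-1, 1, -1, 1], index=list("wxyz"), dtype=float)
        out = quadrant_partition(a, b, 0.0, 0.0)
        assert out == {"region1": ["w"], "region2": ["x"], "region3": ["y"], "region4": ["z"]}

    def test_all_high(self):
        a = pd.Series([1.0, 2.0], index=["p", "q"])
        out = quadrant_partition(a, a, 0.0, 0.0)
        assert out["region2"] == ["p", "q"]

    def test_boundary_counts_low(self):
        a = pd.Series([0.0], index=["p"])
        out = quadrant_partition(a, a, 0.0, 0.0)
        assert out["region3"] == ["p"]
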