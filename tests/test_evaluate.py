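import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from prrx import (bootstrap_metrics, build_grid, classify_metrics,
                  compare_thresholds, cross_validate, roc_auc, sweep,
                  youden_cutoff)


def labels_of(n_af, n_sr):
    return np.array(["AF"] * n_af + ["SR"] * n_sr)


def youden_naive(scores, labels):
    """Exhaustive-search oracle over observed candidate cutoffs, with
    exact rational J so ties break unambiguously toward the largest."""
    from fractions import Fraction

    af = [s for s, l in zip(scores, labels) if l == "AF"]
    sr = [s for s, l in zip(scores, labels) if l == "SR"]
    best = None
    for c in sorted(set(scores)):
        sens = Fraction(sum(1 for v in af if v >= c), len(af))
        spec = Fraction(sum(1 for v in sr if v < c), len(sr))
        j = sens + spec - 1
        if best is None or j > best[1] or (j == best[1] and c > best[0]):
            best = (c, j)
    return best[0], float(best[1])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([3, 4, 1, 2], labels_of(2, 2)) == 1.0

    def test_perfect_inversion(self):
        assert roc_auc([1, 2, 3, 4], labels_of(2, 2)) == 0.0

    def test_interleaved_quarter(self):
        # U enumeration: only the pair (3, 2) ranks AF above SR -> 1/4
        assert roc_auc([1, 3, 2, 4], labels_of(2, 2)) == 0.25

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], np.array(["AF", "AF"]))

    def test_equals_mann_whitney_u_statistic(self):
        rng = np.random.default_rng(8)
        for _ in range(500):
            n1, n0 = rng.integers(3, 30, size=2)
            # coarse integer scores force plenty of ties
            af = rng.integers(0, 12, size=n1).astype(float)
            sr = rng.integers(0, 12, size=n0).astype(float)
            auc = roc_auc(np.r_[af, sr], labels_of(n1, n0))
            u = sps.mannwhitneyu(af, sr).statistic
            assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)


class TestYoudenCutoff:
    def test_separable_groups(self):
        cut, j = youden_cutoff([80, 70, 60, 20, 30, 40], labels_of(3, 3))
        assert cut == 60 and j == 1.0

    def test_identical_multisets_degenerate(self):
        cut, j = youden_cutoff([1, 2, 3, 1, 2, 3], labels_of(3, 3))
        assert j == 0.0
        assert cut == 3  # largest candidate among the all-tied J values

    def test_three_point_example(self):
        cut, j = youden_cutoff([90, 10, 50], labels_of(2, 1))
        assert cut == 90 and j == pytest.approx(0.5)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(9)
        for _ in range(500):
            n1, n0 = rng.integers(2, 25, size=2)
            scores = rng.integers(0, 15, size=n1 + n0).astype(float)
            labels = labels_of(n1, n0)
            got = youden_cutoff(scores, labels)
            expected = youden_naive(scores, labels)
            assert got[0] == expected[0]
            assert got[1] == pytest.approx(expected[1], abs=1e-12)


class TestClassifyMetrics:
    def test_textbook_counts(self):
        scores = np.r_[np.full(90, 80.0), np.full(10, 20.0),
                       np.full(95, 20.0), np.full(5, 80.0)]
        labels = labels_of(100, 100)
        counts, m = classify_metrics(scores, labels, cutoff=50.0)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (90, 10, 95, 5)
        assert m["sensitivity"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(0.95)
        assert m["dor"] == pytest.approx(171.0)

    def test_zero_cell_dor_is_finite(self):
        scores = np.r_[np.full(9, 80.0), [20.0], np.full(10, 20.0)]
        labels = labels_of(10, 10)
        counts, m = classify_metrics(scores, labels, cutoff=50.0)
        assert counts.fp == 0
        # Haldane-Anscombe: (9.5 * 10.5) / (0.5 * 1.5)
        assert m["dor"] == pytest.approx(9.5 * 10.5 / (0.5 * 1.5))
        assert np.isfinite(m["dor"])

    def test_perfect_classification(self):
        scores = np.r_[np.full(10, 90.0), np.full(10, 10.0)]
        _, m = classify_metrics(scores, labels_of(10, 10), cutoff=50.0)
        assert m["accuracy"] == 1.0 and m["f1"] == 1.0

    def test_decision_rule_is_inclusive(self):
        scores = np.array([50.0, 10.0])
        counts, _ = classify_metrics(scores, labels_of(1, 1), cutoff=50.0)
        assert counts.tp == 1  # score == cutoff predicts AF

    def test_nonfinite_cutoff_rejected(self):
        with pytest.raises(ValueError):
            classify_metrics([1.0, 2.0], labels_of(1, 1), np.nan)


class TestBootstrap:
    def test_degenerate_table_zero_width_ci(self):
        scores = np.r_[np.full(20, 100.0), np.zeros(20)]
        res = bootstrap_metrics(scores, labels_of(20, 20), cutoff=50.0,
                                n_boot=200, seed=1)
        for m in ("sensitivity", "specificity"):
            assert res[m].median == 1.0
            assert res[m].ci_high - res[m].ci_low == 0.0

    def test_single_replicate_median(self):
        rng = np.random.default_rng(2)
        scores = np.r_[rng.uniform(60, 100, 30), rng.uniform(0, 40, 30)]
        res = bootstrap_metrics(scores, labels_of(30, 30), cutoff=50.0,
                                n_boot=1, seed=3)
        assert res["accuracy"].median == res["accuracy"].ci_low
        assert res["accuracy"].median == res["accuracy"].ci_high

    def test_seeded_bootstrap_bit_reproducible(self):
        rng = np.random.default_rng(4)
        scores = np.r_[rng.uniform(40, 100, 50), rng.uniform(0, 60, 50)]
        labels = labels_of(50, 50)
        a = bootstrap_metrics(scores, labels, 55.0, n_boot=300, seed=77)
        b = bootstrap_metrics(scores, labels, 55.0, n_boot=300, seed=77)
        assert a == b

    def test_stratified_mode(self):
        scores = np.r_[np.full(5, 90.0), np.full(45, 10.0)]
        res = bootstrap_metrics(scores, labels_of(5, 45), cutoff=50.0,
                                n_boot=100, seed=5, stratified=True)
        assert res["sensitivity"].median == 1.0

    def test_ci_ordering_invariant(self):
        rng = np.random.default_rng(6)
        scores = np.r_[rng.uniform(30, 100, 40), rng.uniform(0, 70, 40)]
        res = bootstrap_metrics(scores, labels_of(40, 40), cutoff=50.0,
                                n_boot=500, seed=6)
        for s in res.values():
            assert s.ci_low <= s.median <= s.ci_high


class TestSweep:
    def test_toy_grid_sizes(self, small_cohort_table):
        for k_max in (1, 2):
            g = build_grid(128, k_max)
            res = sweep(small_cohort_table, g, n_boot=20, seed=1)
            assert len(res) == k_max

    def test_full_sweep_fields_and_lookup(self, small_cohort_table, grid128):
        res = sweep(small_cohort_table, grid128, n_boot=50, seed=2)
        assert len(res) == 25
        df = res.to_frame()
        assert {"x_ms", "auc", "cutoff", "dor_median"} <= set(df.columns)
        assert res["pRR31"].name == "pRR31"
        assert res.best_auc_name in grid128.names

    def test_deterministic_under_seed_and_independent_of_order(
            self, small_cohort_table, grid128):
        a = sweep(small_cohort_table, grid128, n_boot=40, seed=3).to_frame()
        b = sweep(small_cohort_table, grid128, n_boot=40, seed=3).to_frame()
        pd.testing.assert_frame_equal(a, b)
        # a sub-grid sees the same per-threshold streams as the full grid
        sub = sweep(small_cohort_table, build_grid(128, 3), n_boot=40,
                    seed=3).to_frame()
        pd.testing.assert_frame_equal(a.iloc[:3].reset_index(drop=True), sub)

    def test_cutoff_decreases_with_threshold(self, small_cohort_table,
                                             grid128):
        df = sweep(small_cohort_table, grid128, n_boot=1, seed=4).to_frame()
        rho = sps.spearmanr(df["x_ms"], df["cutoff"]).statistic
        assert rho < -0.9
        assert df["cutoff"].iloc[0] > df["cutoff"].iloc[-1]


class TestCompareThresholds:
    def test_same_threshold_identical_distributions(self, small_cohort_table,
                                                    grid128):
        rep = compare_thresholds(small_cohort_table, grid128, 31.25, 31.25,
                                 n_boot=100, seed=1)
        assert (rep.table["p_value"] == 1.0).all()
        assert (rep.table["note"] == "identical_distributions").all()

    def test_deterministic_report(self, small_cohort_table, grid128):
        a = compare_thresholds(small_cohort_table, grid128, 31.25, 54.6875,
                               n_boot=200, seed=9)
        b = compare_thresholds(small_cohort_table, grid128, 31.25, 54.6875,
                               n_boot=200, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.name_a == "pRR31" and a.name_b == "pRR54"

    def test_dominant_threshold_detected(self, grid128):
        # column a separates perfectly, column b is pure noise
        rng = np.random.default_rng(12)
        n = 120
        a = np.r_[np.full(n, 90.0), np.full(n, 10.0)]
        b = rng.uniform(0, 100, 2 * n)
        t = pd.DataFrame({
            "record_id": "r", "start_time_ms": np.arange(2.0 * n),
            "label": ["AF"] * n + ["SR"] * n,
            "pRR7": a, "pRR15": b,
        })
        g = build_grid(128, 2)
        rep = compare_thresholds(t, g, 7.8125, 15.625, n_boot=400, seed=13)
        acc = rep.table.set_index("metric").loc["accuracy"]
        assert acc["median_a"] > acc["median_b"]
        assert acc["p_value"] < 0.001

    def test_off_grid_threshold_rejected(self, small_cohort_table, grid128):
        with pytest.raises(ValueError, match="not on the grid"):
            compare_thresholds(small_cohort_table, grid128, 31.0, 54.6875,
                               n_boot=10, seed=1)


class TestCrossValidate:
    def test_same_dataset_reproduces_in_sample_points(self, small_cohort_table,
                                                      grid128):
        res_a = sweep(small_cohort_table, grid128, n_boot=10, seed=1)
        cutoffs = {r.x_ms: r.cutoff for r in res_a}
        res_b = cross_validate(cutoffs, small_cohort_table, grid128,
                               n_boot=10, seed=2)
        by_x = {r.x_ms: r for r in res_b}
        for r in res_a:
            v = by_x[r.x_ms]
            assert v.cutoff == r.cutoff
            assert v.counts == r.counts
            for m in r.metrics:
                assert v.metrics[m].point == pytest.approx(r.metrics[m].point)

    def test_threshold_mapping_across_sampling_rates(self, small_cohort_table):
        g250 = build_grid(250, 50)
        # only the mapping logic is under test; scores come from a fake table
        rng = np.random.default_rng(3)
        t = pd.DataFrame({"record_id": "r", "start_time_ms": 0.0,
                          "label": ["AF"] * 20 + ["SR"] * 20})
        for name in g250.names:
            t[name] = np.r_[rng.uniform(50, 100, 20), rng.uniform(0, 50, 20)]
        res = cross_validate({31.25: 40.0}, t, g250, n_boot=5, seed=1)
        assert res[0].x_ms == 32.0
        assert res[0].source_x_ms == 31.25
        assert res[0].name == "pRR32"

    def test_empty_validation_table_raises(self, grid128):
        with pytest.raises(ValueError, match="empty"):
            cross_validate({31.25: 50.0}, pd.DataFrame(), grid128)
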