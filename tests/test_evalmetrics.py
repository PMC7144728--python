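"""Median aggregation, Youden cutoff, metric suite and rank statistics.

Independent oracles: brute-force pairwise comparisons for AUC, exhaustive
threshold scans for the Youden index, scikit-learn for confusion-derived
metrics, Pearson correlation for MCC, and closed-form Welch intervals for
the one-vs-rest deltas.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn import metrics as skm

from molsnap.evalmetrics import (ConfusionCounts, aggregate_median, confusion,
                                 delta_vs_rest, mann_whitney, metric_suite,
                                 roc_auc, summarize_rounds, youden_cutoff)


def _random_instance(rng, n=50):
    scores = np.round(rng.random(n), 2)  # rounding forces ties
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    return scores, labels


class TestAggregateMedian:
    def test_median_conventions(self):
        table = pd.DataFrame({
            "id": ["a"] * 3 + ["b"] * 2 + ["c"],
            "prob": [0.2, 0.9, 0.4, 0.2, 0.8, 0.77],
        })
        med = aggregate_median(table)
        assert med["a"] == 0.4      # odd count
        assert med["b"] == 0.5      # even count: mean of central pair
        assert med["c"] == 0.77     # single image

    def test_invariant_to_order_and_duplication(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "id": np.repeat([f"m{i}" for i in range(5)], 27),
            "prob": rng.random(135),
        })
        base = aggregate_median(table)
        shuffled = table.sample(frac=1.0, random_state=1)
        doubled = pd.concat([table, table])
        pd.testing.assert_series_equal(base.sort_index(),
                                       aggregate_median(shuffled).sort_index())
        pd.testing.assert_series_equal(base.sort_index(),
                                       aggregate_median(doubled).sort_index())

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            aggregate_median(pd.DataFrame({"id": [], "prob": []}))


class TestYoudenCutoff:
    def test_separable_returns_smallest_maximizer(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        assert youden_cutoff(scores, labels) == 0.8

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            scores, labels = _random_instance(rng)
            t = youden_cutoff(scores, labels)
            pos, neg = labels == 1, labels == 0

            def j_at(th):
                sens = np.mean(scores[pos] >= th)
                spec = np.mean(scores[neg] < th)
                return sens + spec - 1.0

            best = max(j_at(th) for th in np.unique(scores))
            assert j_at(t) == pytest.approx(best)
            # ties resolved toward the smallest qualifying threshold
            smaller = [th for th in np.unique(scores)
                       if th < t and j_at(th) >= best - 1e-12]
            assert not smaller

    def test_j_range_and_single_class_guard(self):
        rng = np.random.default_rng(1)
        scores, labels = _random_instance(rng)
        t = youden_cutoff(scores, labels)
        c = confusion(scores, labels, t)
        j = c.tp / (c.tp + c.fn) + c.tn / (c.tn + c.fp) - 1.0
        assert 0.0 <= j <= 1.0
        with pytest.raises(ValueError):
            youden_cutoff([0.1, 0.2], [1, 1])


class TestConfusion:
    def test_hand_tally_matches_sklearn(self):
        rng = np.random.default_rng(3)
        scores, labels = _random_instance(rng, n=20)
        t = 0.5
        c = confusion(scores, labels, t)
        tn, fp, fn, tp = skm.confusion_matrix(
            labels, (scores >= t).astype(int)).ravel()
        assert (c.tp, c.fn, c.tn, c.fp) == (tp, fn, tn, fp)

    def test_infinite_threshold_degenerates(self):
        scores, labels = np.array([0.3, 0.9]), np.array([1, 1])
        assert confusion(scores, labels, np.inf).tp == 0
        assert confusion(scores, labels, -np.inf).tp == 2


class TestMetricSuite:
    def test_perfect_classifier(self):
        r = metric_suite(ConfusionCounts(5, 0, 5, 0))
        for m in ("sensitivity", "specificity", "bac", "accuracy",
                  "precision", "recall", "f_measure", "mcc"):
            assert getattr(r, m) == 1.0

    def test_chance_classifier(self):
        r = metric_suite(ConfusionCounts(5, 5, 5, 5))
        assert r.mcc == 0.0 and r.bac == 0.5

    def test_hand_computed_case(self):
        r = metric_suite(ConfusionCounts(tp=8, fn=2, tn=5, fp=5))
        assert r.sensitivity == pytest.approx(0.8)
        assert r.specificity == pytest.approx(0.5)
        assert r.bac == pytest.approx(0.65)
        assert r.accuracy == pytest.approx(0.65)
        assert r.precision == pytest.approx(8 / 13)
        assert r.f_measure == pytest.approx(0.6957, abs=1e-4)
        assert r.mcc == pytest.approx(30 / np.sqrt(13 * 10 * 10 * 7))

    def test_mcc_equals_pearson_of_binary_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            y = rng.integers(0, 2, 40)
            pred = rng.integers(0, 2, 40)
            if len(set(y)) < 2 or len(set(pred)) < 2:
                continue
            tp = int(np.sum((pred == 1) & (y == 1)))
            fp = int(np.sum((pred == 1) & (y == 0)))
            fn = int(np.sum((pred == 0) & (y == 1)))
            tn = int(np.sum((pred == 0) & (y == 0)))
            r = metric_suite(ConfusionCounts(tp, fn, tn, fp))
            assert r.mcc == pytest.approx(np.corrcoef(pred, y)[0, 1])
            assert r.mcc == pytest.approx(skm.matthews_corrcoef(y, pred))

    def test_degenerate_denominators_flagged_as_zero(self):
        r = metric_suite(ConfusionCounts(tp=0, fn=0, tn=4, fp=0))
        assert r.sensitivity == 0.0 and "sensitivity" in r.degenerate
        assert not np.isnan(r.f_measure)


class TestRocAuc:
    def test_separable_and_symmetry(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(scores, labels) == 1.0
        rng = np.random.default_rng(5)
        s, y = _random_instance(rng, 80)
        assert roc_auc(-s, y) == pytest.approx(1.0 - roc_auc(s, y))

    def test_equals_pairwise_probability_and_sklearn(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            s, y = _random_instance(rng, rng.integers(10, 200))
            pos, neg = s[y == 1], s[y == 0]
            pairs = (pos[:, None] > neg[None, :]).mean() \
                + 0.5 * (pos[:, None] == neg[None, :]).mean()
            assert roc_auc(s, y) == pytest.approx(pairs)
            assert roc_auc(s, y) == pytest.approx(skm.roc_auc_score(y, s))

    def test_chance_expectation(self):
        rng = np.random.default_rng(2)
        s = rng.random(1000)
        y = rng.integers(0, 2, 1000)
        assert roc_auc(s, y) == pytest.approx(0.5, abs=0.05)


class TestSummaries:
    def test_identical_rounds_have_zero_sd(self):
        r = metric_suite(ConfusionCounts(5, 0, 5, 0), auc=1.0, cutoff=0.5)
        s = summarize_rounds([r, r, r])
        assert (s["sd"] == 0).all()

    def test_two_round_sample_sd(self):
        rounds = [metric_suite(ConfusionCounts(5, 0, 5, 0), auc=a, cutoff=0.5)
                  for a in (0.9, 1.0)]
        s = summarize_rounds(rounds)
        assert s.loc["auc", "mean"] == pytest.approx(0.95)
        assert s.loc["auc", "sd"] == pytest.approx(0.0707, abs=1e-4)


class TestDeltaVsRest:
    def test_identical_angles_zero_delta(self):
        cmp_ = delta_vs_rest({38: [0.8, 0.8, 0.8], 85: [0.8, 0.8, 0.8]})
        assert (cmp_.table["delta"] == 0).all()

    def test_two_angle_antisymmetry(self):
        cmp_ = delta_vs_rest({38: [0.82, 0.78], 360: [0.62, 0.58]})
        d = cmp_.table["delta"]
        assert d[38] == pytest.approx(0.2) and d[360] == pytest.approx(-0.2)

    def test_welch_interval_matches_closed_form(self):
        rng = np.random.default_rng(4)
        groups = {a: rng.normal(0.8 - 0.02 * i, 0.05, 5)
                  for i, a in enumerate((38, 85, 176))}
        cmp_ = delta_vs_rest(groups)
        own = np.asarray(groups[85])
        rest = np.concatenate([groups[38], groups[176]])
        res = sps.ttest_ind(own, rest, equal_var=False)
        lo, hi = res.confidence_interval(0.95)
        assert cmp_.table.loc[85, "ci_low"] == pytest.approx(lo)
        assert cmp_.table.loc[85, "ci_high"] == pytest.approx(hi)

    def test_small_angle_groups_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            cmp_ = delta_vs_rest({38: [0.8, 0.7], 85: [0.75, 0.72], 360: [0.9]})
        assert 360 not in cmp_.table.index


class TestMannWhitney:
    def test_identical_groups_p_near_one(self):
        _, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_small_sample_exact(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_u_conservation(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=12), rng.normal(1.0, 1.0, size=9)
        ua, _ = mann_whitney(a, b)
        ub, _ = mann_whitney(b, a)
        assert ua + ub == pytest.approx(len(a) * len(b))
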