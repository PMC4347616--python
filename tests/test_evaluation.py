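"""Metrics, curves and paired tests against independent oracles.

Oracles: brute-force loop tallies for confusion counts, concordant-pair
counting for AUC-ROC, threshold enumeration for PR, full 2^n sign
enumeration for the signed-rank test, and sklearn.metrics as an external
cross-check.
"""

import itertools

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from grainforest import (
    Confusion,
    GrainTable,
    auc_pr,
    auc_roc,
    confusion,
    metric_set,
    pr_curve,
    roc_curve,
    score_grid,
    threshold_average,
    undersample_positives,
    wilcoxon_bonferroni,
    wilcoxon_signed_rank,
)
from grainforest.evaluation import curve_points_at, mcc_from_confusion


# ----------------------------------------------------------------- oracles

def pair_count_auc(scores, labels):
    """AUC as the fraction of concordant positive/negative pairs (ties half)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = sum(1.0 if a > b else (0.5 if a == b else 0.0) for a in pos for b in neg)
    return total / (len(pos) * len(neg))


def enumerate_signed_rank_p(a, b):
    """Two-sided p by literal enumeration of all 2^n sign assignments."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product((0, 1), repeat=n)]
    )
    p_le = np.mean(ws <= w + 1e-9)
    p_ge = np.mean(ws >= w - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


# --------------------------------------------------------------- confusion

class TestConfusion:
    def test_perfect_prediction(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 0, 2, 0)

    def test_total_error(self):
        c = confusion([1, 0], [0, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 1, 0, 1)

    def test_matches_loop_tally(self, rng):
        y = rng.integers(0, 2, 20)
        yhat = rng.integers(0, 2, 20)
        c = confusion(y, yhat)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for a, b in zip(y, yhat):
            key = ("t" if a == b else "f") + ("p" if b == 1 else "n")
            tally[key] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tally["tp"], tally["fp"], tally["tn"], tally["fn"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetricSet:
    def test_perfect_classifier(self):
        y = np.array([1, 1, 0, 0])
        ms = metric_set(confusion(y, y), y.astype(float), y)
        assert ms.sensitivity == ms.specificity == ms.precision == ms.npv == 1.0
        assert ms.mcc == 1.0 and ms.auc_roc == 1.0 and ms.auc_pr == 1.0

    def test_all_positive_predictor_on_balanced_data(self):
        y = np.array([1, 1, 0, 0])
        ms = metric_set(confusion(y, np.ones(4, int)))
        assert ms.sensitivity == 1.0
        assert ms.specificity == 0.0
        assert ms.mcc == 0.0  # zero-marginal convention

    def test_mcc_closed_form(self):
        conf = Confusion(tp=40, fp=10, tn=35, fn=15)
        assert mcc_from_confusion(conf) == pytest.approx(0.502518907629606, abs=1e-12)

    def test_mcc_matches_sklearn(self, rng):
        y = rng.integers(0, 2, 60)
        yhat = rng.integers(0, 2, 60)
        assert mcc_from_confusion(confusion(y, yhat)) == pytest.approx(
            matthews_corrcoef(y, yhat), abs=1e-12
        )

    def test_mcc_symmetric_under_class_swap(self, rng):
        y = rng.integers(0, 2, 40)
        yhat = rng.integers(0, 2, 40)
        assert mcc_from_confusion(confusion(y, yhat)) == pytest.approx(
            mcc_from_confusion(confusion(1 - y, 1 - yhat)), abs=1e-12
        )


# ------------------------------------------------------------------ curves

class TestROC:
    def test_perfect_scores(self):
        y = np.array([0, 0, 1, 1])
        assert auc_roc(y.astype(float), y) == 1.0

    def test_constant_scores_give_half(self):
        y = np.array([0, 1, 0, 1])
        assert auc_roc(np.full(4, 0.7), y) == pytest.approx(0.5)

    @pytest.mark.parametrize("n,seed", [(8, 0), (50, 1), (50, 2), (50, 3)])
    def test_trapezoid_equals_pair_counting(self, n, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, n)
        y[0], y[1] = 0, 1  # both classes
        s = np.round(rng.random(n), 2)  # coarse scores force ties
        assert auc_roc(s, y) == pytest.approx(pair_count_auc(s, y), abs=1e-12)
        assert auc_roc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.random(30)
        base = auc_roc(s, y)
        for f in (lambda x: 2 * x + 1, np.exp, lambda x: x**3):
            assert auc_roc(f(s), y) == pytest.approx(base, abs=1e-12)
            assert auc_pr(f(s), y) == pytest.approx(auc_pr(s, y), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([0.1, 0.2], [1, 1])


class TestPR:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        assert auc_pr(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0

    def test_constant_scores_give_prevalence(self):
        y = np.array([1, 0, 0, 0, 1])
        pi = y.mean()
        curve = pr_curve(np.full(5, 0.3), y)
        assert np.allclose(curve.y, pi)
        assert auc_pr(np.full(5, 0.3), y) == pytest.approx(pi)

    def test_matches_threshold_enumeration(self):
        s = np.array([0.9, 0.8, 0.7, 0.6, 0.5, 0.4])
        y = np.array([1, 0, 1, 1, 0, 0])
        pts = []
        for t in sorted(set(s), reverse=True):
            pred = s >= t
            tp = np.sum(pred & (y == 1))
            pts.append((tp / y.sum(), tp / pred.sum()))
        expected = np.trapezoid(
            [pts[0][1]] + [p for _, p in pts], [0.0] + [r for r, _ in pts]
        )
        assert auc_pr(s, y) == pytest.approx(expected, abs=1e-12)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([0.1, 0.2], [0, 0])


class TestThresholdAverage:
    def runs(self, rng, n_runs=10, n=40):
        out = []
        for _ in range(n_runs):
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = np.round(rng.random(n) * 10) / 10
            out.append((s, y))
        return out

    def test_identical_runs_have_zero_band(self, rng):
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        s = rng.random(30)
        av = threshold_average([(s, y), (s, y), (s, y)], score_grid(10))
        assert np.allclose(av.y_lo, av.y_hi)
        assert np.allclose(av.y_mean, av.y_lo)

    def test_two_runs_average_is_midpoint(self):
        y = np.array([0, 0, 1, 1])
        s1 = np.array([0.1, 0.2, 0.8, 0.9])
        s2 = np.array([0.1, 0.9, 0.2, 0.8])
        av = threshold_average([(s1, y), (s2, y)], np.array([0.5]))
        x1, y1 = curve_points_at(s1, y, [0.5])
        x2, y2 = curve_points_at(s2, y, [0.5])
        assert av.y_mean[0] == pytest.approx((y1[0] + y2[0]) / 2)
        assert av.x_mean[0] == pytest.approx((x1[0] + x2[0]) / 2)

    @pytest.mark.parametrize("kind", ["roc", "pr"])
    def test_matches_brute_force_recompute(self, rng, kind):
        runs = self.runs(rng)
        grid = score_grid(20)
        av = threshold_average(runs, grid, kind=kind)
        for ti, t in enumerate(grid):
            xs, ys = [], []
            for s, y in runs:
                pred = s >= t
                tp = np.sum(pred & (y == 1))
                fp = np.sum(pred & (y == 0))
                P = y.sum()
                N = len(y) - P
                if kind == "roc":
                    xs.append(fp / N)
                    ys.append(tp / P)
                else:
                    xs.append(tp / P)
                    ys.append(tp / pred.sum() if pred.any() else pr_curve(s, y).y[0])
            assert av.x_mean[ti] == pytest.approx(np.mean(xs), abs=1e-12)
            assert av.y_mean[ti] == pytest.approx(np.mean(ys), abs=1e-12)
            assert av.y_lo[ti] == pytest.approx(np.percentile(ys, 2.5), abs=1e-12)

    def test_band_contains_mean(self, rng):
        av = threshold_average(self.runs(rng), score_grid(10))
        assert (av.y_lo <= av.y_mean + 1e-12).all()
        assert (av.y_mean <= av.y_hi + 1e-12).all()

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            threshold_average(self.runs(rng, 2), np.array([]))


class TestUndersample:
    def make_table(self, n_pos, n_neg):
        n = n_pos + n_neg
        labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
        return GrainTable(np.arange(n, dtype=float).reshape(-1, 1), labels, np.arange(n).astype(str))

    def test_realistic_prevalence_keeps_two_positives(self, rng):
        t = self.make_table(100, 18_000)
        out = undersample_positives(t, 1 / 9000, rng)
        assert (out.labels == 1).sum() == 2
        assert (out.labels == 0).sum() == 18_000

    def test_target_equal_to_current_rate_is_identity(self, rng):
        t = self.make_table(10, 90)
        out = undersample_positives(t, 0.1, rng)
        assert out.n == t.n

    def test_count_deterministic_identities_vary(self):
        t = self.make_table(500, 2000)
        kept = [
            frozenset(undersample_positives(t, 0.01, np.random.default_rng(s)).grain_ids[
                undersample_positives(t, 0.01, np.random.default_rng(s)).labels == 1
            ])
            for s in range(5)
        ]
        assert len({len(k) for k in kept}) == 1  # constant positive count
        assert len(set(kept)) > 1  # different identities

    def test_target_above_current_rejected(self, rng):
        t = self.make_table(10, 90)
        with pytest.raises(ValueError):
            undersample_positives(t, 0.5, rng)


class TestWilcoxon:
    def test_identical_pairs_not_significant(self):
        a = np.arange(10.0)
        res = wilcoxon_bonferroni({"m": (a, a.copy())}, n_comparisons=3)
        assert res["m"]["p_adjusted"] == 1.0
        assert not res["m"]["significant"]

    @pytest.mark.parametrize("seed,n", [(0, 6), (1, 9), (2, 12), (3, 12)])
    def test_exact_p_matches_sign_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        a = np.round(rng.random(n), 1)  # rounding forces tied differences
        b = np.round(rng.random(n), 1)
        _, p = wilcoxon_signed_rank(a, b)
        assert p == pytest.approx(enumerate_signed_rank_p(a, b), abs=1e-12)

    def test_large_n_matches_scipy_approximation(self, rng):
        a = rng.random(40)
        b = a + rng.normal(0.05, 0.1, 40)
        _, p = wilcoxon_signed_rank(a, b)
        ref = stats.wilcoxon(a, b, correction=False, method="approx").pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_bonferroni_multiplies_and_caps(self, rng):
        a = rng.random(30)
        b = a + 0.2
        res = wilcoxon_bonferroni({"m": (a, b)}, n_comparisons=7)
        assert res["m"]["p_adjusted"] == pytest.approx(min(1.0, 7 * res["m"]["p_raw"]))
        res_capped = wilcoxon_bonferroni({"m": (a, a.copy() + 1e-15)}, n_comparisons=7)
        assert res_capped["m"]["p_adjusted"] <= 1.0


def test_pr_dominance_implies_roc_dominance(rng):
    """On a fixed test set, PR-space dominance carries over to ROC space."""
    y = rng.integers(0, 2, 200)
    y[:2] = [0, 1]
    grid = score_grid(50)
    seen_dominance = 0
    for _ in range(20):
        s_good = y + rng.normal(0, 0.4, 200)
        s_bad = y + rng.normal(0, 1.2, 200)
        ra, rb = curve_points_at(s_good, y, grid, "pr"), curve_points_at(s_bad, y, grid, "pr")
        # compare precision at matched recall by interpolation on the recall axis
        recalls = np.linspace(0.05, 0.95, 19)
        pa = np.interp(recalls, ra[0][np.argsort(ra[0])], ra[1][np.argsort(ra[0])])
        pb = np.interp(recalls, rb[0][np.argsort(rb[0])], rb[1][np.argsort(rb[0])])
        if (pa >= pb).all():
            seen_dominance += 1
            fa, fb = curve_points_at(s_good, y, grid, "roc"), curve_points_at(s_bad, y, grid, "roc")
            fprs = np.linspace(0.05, 0.95, 19)
            ta = np.interp(fprs, fa[0][np.argsort(fa[0])], fa[1][np.argsort(fa[0])])
            tb = np.interp(fprs, fb[0][np.argsort(fb[0])], fb[1][np.argsort(fb[0])])
            assert (ta >= tb - 1e-9).all()
    assert seen_dominance > 0
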