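"""Classification metrics, ROC/PR curves with threshold averaging, and paired tests.

Forest scores live on the lattice {0, 1/t, ..., 1}, so curves are swept over
score thresholds with the predicate ``score >= threshold`` and repetitions
are aligned *by threshold*: the averaged curve takes, at each threshold in a
shared grid, the mean operating point over runs plus an empirical 95% band
(2.5/97.5 percentiles). This is threshold averaging, applied identically to
ROC and PR curves.

Degenerate-denominator conventions: MCC is 0 when any confusion marginal is
zero; PR precision at zero recall is anchored at the precision of the
top-scored threshold, avoiding a 0/0 corner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .table import GrainTable

__all__ = [
    "Confusion",
    "MetricSet",
    "METRIC_ORDER",
    "METRIC_DISPLAY",
    "confusion",
    "metric_set",
    "roc_curve",
    "auc_roc",
    "pr_curve",
    "auc_pr",
    "Curve",
    "AveragedCurve",
    "curve_points_at",
    "threshold_average",
    "score_grid",
    "undersample_positives",
    "wilcoxon_signed_rank",
    "wilcoxon_bonferroni",
]

METRIC_ORDER = ["sensitivity", "specificity", "precision", "npv", "mcc", "auc_roc", "auc_pr"]
METRIC_DISPLAY = {
    "sensitivity": "Sensitivity",
    "specificity": "Specificity",
    "precision": "Precision",
    "npv": "NPV",
    "mcc": "MCC",
    "auc_roc": "AUC-ROC",
    "auc_pr": "AUC-PR",
    "accuracy": "Accuracy",
}


@dataclass(frozen=True)
class Confusion:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    mcc: float
    accuracy: float
    auc_roc: float
    auc_pr: float

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "npv": self.npv,
            "mcc": self.mcc,
            "accuracy": self.accuracy,
            "auc_roc": self.auc_roc,
            "auc_pr": self.auc_pr,
        }


def _as_binary(a) -> np.ndarray:
    a = np.asarray(a).astype(int)
    if not np.isin(a, (0, 1)).all():
        raise ValueError("labels/predictions must be binary (0/1)")
    return a


def confusion(labels, predictions) -> Confusion:
    """Exact confusion counts for binary labels and hard predictions."""
    y = _as_binary(labels)
    yhat = _as_binary(predictions)
    if y.shape != yhat.shape:
        raise ValueError("labels and predictions must have equal length")
    return Confusion(
        tp=int(np.sum((y == 1) & (yhat == 1))),
        fp=int(np.sum((y == 0) & (yhat == 1))),
        tn=int(np.sum((y == 0) & (yhat == 0))),
        fn=int(np.sum((y == 1) & (yhat == 0))),
    )


def _safe_div(num: float, den: float, default: float = 0.0) -> float:
    return num / den if den > 0 else default


def mcc_from_confusion(conf: Confusion) -> float:
    """Matthews correlation coefficient; 0 when any marginal count is zero."""
    tp, fp, tn, fn = conf.tp, conf.fp, conf.tn, conf.fn
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom2 == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom2))


def metric_set(conf: Confusion, scores=None, labels=None) -> MetricSet:
    """Threshold metrics from a confusion plus ranking AUCs from scores.

    When ``scores``/``labels`` are omitted, the AUCs are reported as NaN.
    """
    if scores is not None and labels is not None:
        roc = auc_roc(scores, labels)
        pr = auc_pr(scores, labels)
    else:
        roc = pr = float("nan")
    return MetricSet(
        sensitivity=_safe_div(conf.tp, conf.tp + conf.fn),
        specificity=_safe_div(conf.tn, conf.tn + conf.fp),
        precision=_safe_div(conf.tp, conf.tp + conf.fp),
        npv=_safe_div(conf.tn, conf.tn + conf.fn),
        mcc=mcc_from_confusion(conf),
        accuracy=_safe_div(conf.tp + conf.tn, conf.n),
        auc_roc=roc,
        auc_pr=pr,
    )


# ------------------------------------------------------------------- curves

@dataclass
class Curve:
    """Operating points of one run: for ROC x=FPR, y=TPR; for PR x=recall, y=precision."""

    thresholds: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def auc(self) -> float:
        order = np.argsort(self.x, kind="stable")
        return float(np.trapezoid(self.y[order], self.x[order]))


def _threshold_counts(scores, labels):
    """Distinct score thresholds (descending) with tp/fp counts for score >= t."""
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # last index of each block of equal scores
    last = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tps = np.cumsum(y_sorted)[last]
    fps = (last + 1) - tps
    return s_sorted[last], tps.astype(float), fps.astype(float)


def roc_curve(scores, labels) -> Curve:
    """ROC points over all distinct score thresholds, anchored at (0, 0)."""
    y = _as_binary(labels)
    P = int(y.sum())
    N = len(y) - P
    if P == 0 or N == 0:
        raise ValueError("ROC curve requires both classes present")
    thr, tps, fps = _threshold_counts(scores, y)
    return Curve(
        thresholds=np.r_[np.inf, thr],
        x=np.r_[0.0, fps / N],
        y=np.r_[0.0, tps / P],
    )


def auc_roc(scores, labels) -> float:
    """Trapezoidal area under the ROC curve (equals the normalised Mann-Whitney U)."""
    return roc_curve(scores, labels).auc()


def pr_curve(scores, labels) -> Curve:
    """Precision-recall points over the same threshold sweep as the ROC curve.

    The zero-recall end is anchored at the precision of the highest-score
    threshold.
    """
    y = _as_binary(labels)
    P = int(y.sum())
    if P == 0:
        raise ValueError("PR curve requires at least one positive")
    thr, tps, fps = _threshold_counts(scores, y)
    precision = tps / (tps + fps)
    recall = tps / P
    return Curve(
        thresholds=np.r_[np.inf, thr],
        x=np.r_[0.0, recall],
        y=np.r_[precision[0], precision],
    )


def auc_pr(scores, labels) -> float:
    """Trapezoidal area under the precision-recall curve over recall."""
    return pr_curve(scores, labels).auc()


def score_grid(n_trees: int) -> np.ndarray:
    """The score lattice {0, 1/t, ..., 1} induced by a t-tree voting ensemble."""
    return np.linspace(0.0, 1.0, n_trees + 1)


def curve_points_at(scores, labels, grid, kind: str = "roc"):
    """Operating point of one run at each grid threshold (predicate score >= t).

    For PR, thresholds above the maximal score yield no positive predictions;
    their precision is anchored at the top-threshold precision.
    """
    s = np.asarray(scores, dtype=float)
    y = _as_binary(labels)
    grid = np.asarray(grid, dtype=float)
    P = int(y.sum())
    N = len(y) - P
    order = np.argsort(s, kind="stable")
    s_sorted = s[order]
    pos_cum = np.cumsum(y[order])  # positives with score <= s_sorted[i]
    # number of examples with score >= t
    first_ge = np.searchsorted(s_sorted, grid, side="left")
    n_ge = len(s) - first_ge
    pos_below = np.where(first_ge > 0, pos_cum[np.clip(first_ge - 1, 0, None)], 0)
    tp = P - pos_below
    fp = n_ge - tp
    if kind == "roc":
        if P == 0 or N == 0:
            raise ValueError("ROC requires both classes present")
        return fp / N, tp / P
    if kind == "pr":
        if P == 0:
            raise ValueError("PR requires at least one positive")
        anchor = pr_curve(s, y).y[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            precision = np.where(n_ge > 0, tp / np.maximum(n_ge, 1), anchor)
        return tp / P, precision
    raise ValueError(f"unknown curve kind {kind!r}")


@dataclass
class AveragedCurve:
    """Threshold-averaged curve across repetitions with empirical 95% bands."""

    thresholds: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    x_lo: np.ndarray
    x_hi: np.ndarray
    y_lo: np.ndarray
    y_hi: np.ndarray
    n_runs: int
    kind: str = "roc"


def threshold_average(runs, grid, kind: str = "roc") -> AveragedCurve:
    """Average per-run operating points at each shared score threshold.

    Parameters
    ----------
    runs : list of (scores, labels) pairs
        One entry per repetition.
    grid : array-like
        Shared score thresholds, e.g. :func:`score_grid` of the ensemble size.
    kind : {"roc", "pr"}
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be non-empty")
    if len(runs) < 2:
        raise ValueError("threshold averaging needs at least two runs")
    xs, ys = [], []
    for scores, labels in runs:
        x, y = curve_points_at(scores, labels, grid, kind=kind)
        xs.append(x)
        ys.append(y)
    X = np.vstack(xs)
    Y = np.vstack(ys)
    return AveragedCurve(
        thresholds=grid,
        x_mean=X.mean(axis=0),
        y_mean=Y.mean(axis=0),
        x_lo=np.percentile(X, 2.5, axis=0),
        x_hi=np.percentile(X, 97.5, axis=0),
        y_lo=np.percentile(Y, 2.5, axis=0),
        y_hi=np.percentile(Y, 97.5, axis=0),
        n_runs=len(runs),
        kind=kind,
    )


# ------------------------------------------------------- prevalence adjustment

def undersample_positives(table: GrainTable, target_pos_rate: float, rng: np.random.Generator) -> GrainTable:
    """Subsample positives (without replacement) down to a target prevalence.

    Mimics a realistic deployment class distribution (e.g. one pathogenic
    variant per ~9000 candidates) by thinning positives while leaving
    negatives untouched. The retained positive count is
    ``floor(rate * n_neg / (1 - rate))``, never below one.
    """
    if not 0.0 < target_pos_rate < 1.0:
        raise ValueError("target_pos_rate must lie in (0, 1)")
    pos_idx = np.flatnonzero(table.labels == 1)
    neg_idx = np.flatnonzero(table.labels == 0)
    current = len(pos_idx) / table.n
    if target_pos_rate > current:
        raise ValueError(
            f"target rate {target_pos_rate} exceeds current positive rate {current:.6g}"
        )
    # tiny epsilon guards the floor against roundoff when target == current rate
    n_keep = max(1, int(np.floor(target_pos_rate * len(neg_idx) / (1.0 - target_pos_rate) + 1e-9)))
    keep_pos = rng.choice(pos_idx, size=min(n_keep, len(pos_idx)), replace=False)
    keep = np.sort(np.concatenate([neg_idx, keep_pos]))
    return table.subset(keep)


# ------------------------------------------------------------- paired testing

def _exact_signed_rank_p(w: float, ranks: np.ndarray) -> float:
    """Two-sided exact p for the signed-rank statistic W+ = sum of positive ranks.

    The null distribution is built by dynamic programming over doubled ranks
    (tie-averaged ranks are half-integers), equivalent to enumerating all
    2^n sign assignments.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.round(2 * w))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; tied absolute differences receive average
    ranks. The exact null distribution is used up to 25 informative pairs,
    the normal approximation with tie correction above. Returns
    ``(W+, p)``; all-zero differences give ``(0, 1)``.
    """
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= 25:
        return w, _exact_signed_rank_p(w, ranks)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w - mean) / np.sqrt(var)
    return w, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def wilcoxon_bonferroni(paired_metrics: dict, n_comparisons: int, alpha: float = 0.05) -> dict:
    """Wilcoxon signed-rank per metric with Bonferroni-adjusted p-values.

    Parameters
    ----------
    paired_metrics : dict
        Maps metric name to a pair ``(values_a, values_b)`` of equal-length
        paired samples (one entry per repetition).
    n_comparisons : int
        Bonferroni multiplier m; adjusted p = min(1, m * raw p).

    Returns
    -------
    dict mapping metric name to
    ``{"statistic", "p_raw", "p_adjusted", "significant"}``.
    """
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    out = {}
    for name, (a, b) in paired_metrics.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"metric {name!r}: paired samples differ in length")
        w, p = wilcoxon_signed_rank(a, b)
        p_adj = min(1.0, p * n_comparisons)
        out[name] = {
            "statistic": w,
            "p_raw": p,
            "p_adjusted": p_adj,
            "significant": bool(p_adj < alpha),
        }
    return out
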