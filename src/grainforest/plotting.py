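"""Optional plotting helpers (thin wrappers over matplotlib)."""

from __future__ import annotations

import numpy as np

from .evaluation import AveragedCurve


def plot_averaged_curve(curve: AveragedCurve, ax=None, label: str | None = None, color=None):
    """Mean ROC/PR curve with its shaded empirical 95% band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    order = np.argsort(curve.x_mean, kind="stable")
    ax.plot(curve.x_mean[order], curve.y_mean[order], label=label, color=color)
    ax.fill_between(
        curve.x_mean[order], curve.y_lo[order], curve.y_hi[order], alpha=0.25, color=color
    )
    if curve.kind == "roc":
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
    else:
        ax.set_xlabel("Recall")
        ax.set_ylabel("Precision")
    if label:
        ax.legend()
    return ax


def plot_binsize_trend(df, metric: str = "accuracy", ax=None):
    """Mean +/- empirical 95% interval of a metric versus partition size, per scheme."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for scheme, group in df.groupby("scheme"):
        g = group.groupby("partition_size")[metric]
        mean = g.mean()
        lo = g.quantile(0.025)
        hi = g.quantile(0.975)
        ax.errorbar(
            mean.index, mean.values,
            yerr=[mean - lo, hi - mean],
            marker="o", capsize=3, label=scheme,
        )
    ax.set_xscale("log")
    ax.set_xlabel("partition size |P|")
    ax.set_ylabel(metric)
    ax.legend()
    return ax
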