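"""Report figures: distance-by-category box plot and ROC curve."""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .capture import ThresholdCategory
from .stats import auc_mann_whitney

__all__ = ["plot_distance_by_category", "plot_roc"]


def plot_distance_by_category(records, path=None):
    cats = records["category"].to_numpy(dtype=int)
    d = records["distance_mm"].to_numpy(dtype=float)
    groups = [d[cats == int(c)] for c in ThresholdCategory]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.boxplot([g for g in groups if len(g)], tick_labels=[
        c.label for c, g in zip(ThresholdCategory, groups) if len(g)])
    ax.set_ylabel("distance to nerve (mm)")
    ax.set_xlabel("capture-threshold category")
    ax.tick_params(axis="x", labelrotation=20)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_roc(records, distance_cutoff_mm: float = 10.0, path=None):
    cats = records["category"].to_numpy(dtype=int)
    pos = records["distance_mm"].to_numpy(dtype=float) > distance_cutoff_mm
    # empirical ROC points over the ordinal cutoffs
    fpr, tpr = [1.0], [1.0]
    for k in range(5):
        pred = cats > k - 1  # predict positive when category >= k
        tpr.append(float(np.mean(pred[pos])))
        fpr.append(float(np.mean(pred[~pos])))
    order = np.argsort(fpr)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(np.asarray(fpr)[order], np.asarray(tpr)[order], "o-")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"AUC = {auc_mann_whitney(pos, cats):.3f}")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
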