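"""Small plotting helpers (ROC curves, segment profiles, feature boxplots)."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_roc", "plot_segment_profiles", "plot_feature_box"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_roc(result, label: str | None = None, ax=None):
    """Plot an ROC curve from a :class:`~cardiomad.classify.ROCResult`."""
    ax = _axes(ax)
    fpr = np.concatenate([[0.0], 1.0 - result.specificity, [1.0]])
    tpr = np.concatenate([[0.0], result.sensitivity, [1.0]])
    order = np.argsort(fpr, kind="stable")
    txt = f"AUC = {result.auc:.2f}" if label is None else f"{label} (AUC = {result.auc:.2f})"
    ax.plot(fpr[order], tpr[order], label=txt)
    ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    return ax


def plot_segment_profiles(segments, value: str = "mean_T2_ms", ax=None,
                          log: bool = False):
    """One line per subject over the 16 segments (segmental T2 or pixel-SD)."""
    ax = _axes(ax)
    for sid, sub in segments.groupby("subject_id"):
        sub = sub.sort_values("segment_id")
        y = sub[value].to_numpy(dtype=float)
        if log:
            y = np.log(y)
        ax.plot(sub["segment_id"], y, alpha=0.5, lw=0.8)
    ax.set_xlabel("AHA segment")
    ax.set_ylabel(("log " if log else "") + value)
    return ax


def plot_feature_box(features, feature: str, label_col: str = "label", ax=None):
    """Box-whisker comparison of one feature between the two groups."""
    ax = _axes(ax)
    groups = [g for _, g in features.groupby(label_col)]
    ax.boxplot([g[feature] for g in groups],
               tick_labels=[str(g[label_col].iloc[0]) for g in groups])
    ax.set_ylabel(feature)
    return ax
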