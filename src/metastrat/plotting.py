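"""Matplotlib views of fitted stratification results."""

from __future__ import annotations

import numpy as np


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_consensus(results, ax=None):
    """Consensus matrix heatmap with samples ordered by first-step cluster."""
    ax = _get_ax(ax)
    labels = results.first_labels
    order = labels.sort_values(kind="stable").index
    mat = results.consensus.consensus.loc[order, order]
    im = ax.imshow(mat.to_numpy(), cmap="viridis", vmin=0, vmax=1)
    ax.set_title("Consensus matrix (cluster-ordered)")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.figure.colorbar(im, ax=ax, label="co-clustering frequency")
    return ax


def plot_silhouette(results, ax=None):
    """Per-sample silhouette widths grouped by first-step cluster."""
    ax = _get_ax(ax)
    labels = results.first_labels
    widths = results.silhouette_samples
    pos = 0
    for c in sorted(labels.unique(), key=lambda x: (len(x), x)):
        vals = np.sort(widths[labels == c].to_numpy())[::-1]
        ax.bar(np.arange(pos, pos + len(vals)), vals, width=1.0, label=c)
        pos += len(vals) + 1
    ax.axhline(0, color="k", lw=0.5)
    ax.set_ylabel("silhouette width")
    ax.set_xticks([])
    ax.legend(fontsize="small", ncol=2)
    return ax


def plot_roc(roc_results, ax=None):
    """Macro-averaged per-class ROC curves for each evaluated feature set."""
    ax = _get_ax(ax)
    for name, res in roc_results.items():
        for cls, curve in res.curves.items():
            ax.plot(curve["fpr"], curve["tpr"], alpha=0.6,
                    label=f"{name}/{cls} (AUC={res.auc_per_class[cls]:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize="x-small")
    return ax
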