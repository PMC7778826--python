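"""Optional figure rendering (ROC, precision-recall, MDA, partial dependence).

All functions write SVG/PNG to a path and return the matplotlib figure; the
rest of the package never imports matplotlib.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.metrics import roc_curve

from .evaluation import MDARanking, precision_recall_points, roc_auc


def plot_roc(y_true, scores, path: str | Path):
    fpr, tpr, _ = roc_curve(np.asarray(y_true, dtype=int), np.asarray(scores, dtype=float))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(fpr, tpr, lw=1.5, label=f"AUC = {roc_auc(y_true, scores):.3f}")
    ax.plot([0, 1], [0, 1], "--", color="grey", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return fig


def plot_precision_recall(y_true, scores, path: str | Path):
    pts = precision_recall_points(y_true, scores)
    precision, recall = zip(*pts)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(recall, precision, lw=1.5)
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return fig


def plot_mda(ranking: MDARanking, path: str | Path, top: int = 20):
    names = ranking.ranking[:top]
    values = [ranking.mda[f] for f in names]
    fig, ax = plt.subplots(figsize=(5, 0.3 * len(names) + 1))
    ax.barh(range(len(names)), values)
    ax.set_yticks(range(len(names)), names)
    ax.invert_yaxis()
    ax.set_xlabel("mean decrease in accuracy (percentage points)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return fig


def plot_partial_dependence(grid, curve, feature: str, path: str | Path):
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(np.asarray(grid, dtype=float), np.asarray(curve, dtype=float), lw=1.5)
    ax.set_xlabel(feature)
    ax.set_ylabel("mean predicted score")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return fig
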