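"""Figure artifacts: ROC curves, confusion heatmaps, learning curves.

The numerical tables are the evaluation contract; these plots are
cosmetic companions written to files for reports.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .evaluation import EvalReport

__all__ = ["save_roc_plot", "save_confusion_heatmap", "save_learning_curve_plot"]


def save_roc_plot(report: EvalReport, path: str | Path) -> Path:
    """One-vs-rest ROC curves for every evaluable class of one model."""
    fig, ax = plt.subplots(figsize=(5, 5))
    for name, curve in report.roc_curves.items():
        auc = report.per_class_auc.get(name, float("nan"))
        ax.plot(curve["fpr"], curve["tpr"], label=f"{name} (AUC {auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(f"{report.model}: mean AUC {report.mean_auc:.3f}")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def save_confusion_heatmap(report: EvalReport, path: str | Path) -> Path:
    """Confusion matrix heatmap (rows true, columns predicted)."""
    matrix = report.confusion_matrix
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(matrix, cmap="Blues")
    ticks = np.arange(len(report.class_names))
    ax.set_xticks(ticks, report.class_names, rotation=45, ha="right", fontsize=7)
    ax.set_yticks(ticks, report.class_names, fontsize=7)
    for i in range(matrix.shape[0]):
        for j in range(matrix.shape[1]):
            ax.text(j, i, str(matrix[i, j]), ha="center", va="center", fontsize=8)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    ax.set_title(f"{report.model}: confusion matrix (n={report.n})")
    fig.colorbar(im, fraction=0.046)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path


def save_learning_curve_plot(curve: pd.DataFrame, title: str, path: str | Path) -> Path:
    """Learning curve with a ±1 sd band around the validation accuracy."""
    fig, ax = plt.subplots(figsize=(5.5, 4))
    ax.plot(curve["size"], curve["train_accuracy_mean"], "o-", label="train")
    ax.plot(curve["size"], curve["validation_accuracy_mean"], "s-", label="validation")
    ax.fill_between(
        curve["size"],
        curve["validation_accuracy_mean"] - curve["validation_accuracy_sd"],
        curve["validation_accuracy_mean"] + curve["validation_accuracy_sd"],
        alpha=0.2,
    )
    ax.set_xlabel("Training examples")
    ax.set_ylabel("Accuracy")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
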