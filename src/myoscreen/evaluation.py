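"""Evaluation machinery: multiclass metrics, one-vs-rest ROC, learning
curves, and three confidence-interval procedures.

Point metrics (accuracy, weighted precision/recall/F1, per-class accuracy,
confusion matrix) follow standard multiclass definitions with true-class
support as the weighting.  AUC is one-vs-rest, computed with the tie-aware
rank (Mann–Whitney) statistic, and the mean AUC is the unweighted mean
over classes that have at least one positive and one negative case (a
support-weighted variant is available by flag).

Three interval procedures are provided, each tagged on the result:

* percentile bootstrap over case resamples (default B = 1000, seeded);
* the Wilson score interval for proportion metrics;
* the Hanley–McNeil normal approximation for AUC, with
  Q1 = A/(2−A) and Q2 = 2A²/(1+A).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support, roc_curve
from sklearn.model_selection import StratifiedShuffleSplit

from .rules import CATEGORIES

__all__ = [
    "ConfidenceInterval",
    "EvalReport",
    "multiclass_metrics",
    "confusion",
    "roc_ovr",
    "bootstrap_ci",
    "wilson_ci",
    "hanley_mcneil_ci",
    "learning_curve",
    "evaluate_model",
]


@dataclass(frozen=True)
class ConfidenceInterval:
    """An interval with its construction method tag."""

    lower: float
    upper: float
    method: str
    level: float = 0.95
    redraws: int = 0

    def __iter__(self):
        yield self.lower
        yield self.upper

    def __contains__(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def _as_codes(y, labels: Sequence) -> np.ndarray:
    index = {label: i for i, label in enumerate(labels)}
    arr = np.asarray(y)
    try:
        return np.array([index[v] for v in arr])
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}; expected one of {list(labels)}")


def _resolve_labels(y_true, y_pred, labels) -> list:
    if labels is not None:
        return list(labels)
    observed = set(np.asarray(y_true).tolist()) | set(np.asarray(y_pred).tolist())
    if observed <= set(CATEGORIES):
        return [c for c in CATEGORIES if c in observed] if observed != set(CATEGORIES) else list(CATEGORIES)
    return sorted(observed)


def multiclass_metrics(
    y_true, y_pred, labels: Sequence | None = None
) -> dict[str, object]:
    """Accuracy, support-weighted precision/recall/F1, and per-class accuracy.

    Per-class accuracy is the within-class hit rate (the confusion-matrix
    diagonal over the row sum).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("cannot compute metrics on empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label vectors must be equal length")
    labels = _resolve_labels(y_true, y_pred, labels)
    matrix = confusion(y_true, y_pred, labels=labels)
    accuracy = float(np.trace(matrix) / matrix.sum())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        precision, recall, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, average="weighted", zero_division=0
        )
    row_sums = matrix.sum(axis=1)
    per_class = {
        str(label): (float(matrix[i, i] / row_sums[i]) if row_sums[i] else float("nan"))
        for i, label in enumerate(labels)
    }
    return {
        "accuracy": accuracy,
        "precision_weighted": float(precision),
        "recall_weighted": float(recall),
        "f1_weighted": float(f1),
        "per_class_accuracy": per_class,
        "support": {str(label): int(s) for label, s in zip(labels, row_sums)},
    }


def confusion(y_true, y_pred, labels: Sequence | None = None) -> np.ndarray:
    """Count matrix with rows = true classes, columns = predicted classes.

    Rows/columns follow the canonical clinical order (hyperopia first,
    high myopia last) when the labels are the five screening categories.
    """
    labels = _resolve_labels(y_true, y_pred, labels)
    return _sk_confusion(y_true, y_pred, labels=labels)


def _auc_rank(scores: np.ndarray, positives: np.ndarray) -> float:
    """Tie-aware one-vs-rest AUC via the rank-sum statistic."""
    n_pos = int(positives.sum())
    n_neg = len(positives) - n_pos
    ranks = stats.rankdata(scores)  # average ranks on ties
    rank_sum = float(ranks[positives].sum())
    return (rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_ovr(
    y_true,
    scores: np.ndarray,
    labels: Sequence | None = None,
    weighted: bool = False,
) -> dict[str, object]:
    """One-vs-rest AUC per class and their mean.

    ``scores`` is an (n, k) matrix of per-class scores (probabilities or
    decision-function values).  Classes without both a positive and a
    negative case are excluded from the mean with a warning.  The mean is
    unweighted over included classes unless ``weighted``.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true)
    if scores.ndim != 2 or scores.shape[0] != len(y_true):
        raise ValueError("scores must be an (n, n_classes) matrix aligned with y_true")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    labels = list(labels) if labels is not None else list(CATEGORIES)
    if scores.shape[1] != len(labels):
        raise ValueError(
            f"scores has {scores.shape[1]} columns for {len(labels)} classes"
        )
    codes = _as_codes(y_true, labels)
    per_class: dict[str, float] = {}
    supports: list[int] = []
    aucs: list[float] = []
    for i, label in enumerate(labels):
        positives = codes == i
        n_pos = int(positives.sum())
        if n_pos == 0 or n_pos == len(codes):
            warnings.warn(
                f"class {label!r} has no positives or no negatives; excluded from mean AUC",
                UserWarning,
                stacklevel=2,
            )
            per_class[str(label)] = float("nan")
            continue
        auc = _auc_rank(scores[:, i], positives)
        per_class[str(label)] = auc
        aucs.append(auc)
        supports.append(n_pos)
    if not aucs:
        raise ValueError("no class with both positives and negatives; AUC undefined")
    if weighted:
        mean_auc = float(np.average(aucs, weights=supports))
    else:
        mean_auc = float(np.mean(aucs))
    return {"per_class_auc": per_class, "mean_auc": mean_auc}


def bootstrap_ci(
    metric: Callable[..., float],
    *arrays,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    max_redraws: int = 100,
) -> ConfidenceInterval:
    """Percentile bootstrap CI over case resamples.

    ``metric`` is called as ``metric(a1[idx], a2[idx], ...)`` on each of
    the ``B`` index resamples.  A resample on which the metric is
    undefined (raises, or returns NaN — e.g. a single-class draw) is
    redrawn; the number of redraws is recorded on the interval.
    Bit-reproducible under a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not arrays or len(np.asarray(arrays[0])) == 0:
        raise ValueError("bootstrap_ci needs non-empty input arrays")
    arrays = tuple(np.asarray(a) for a in arrays)
    n = len(arrays[0])
    rng = np.random.default_rng(seed)
    values = np.empty(B)
    redraws = 0
    for b in range(B):
        for _ in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    value = float(metric(*(a[idx] for a in arrays)))
            except Exception:
                value = float("nan")
            if np.isfinite(value):
                break
            redraws += 1
        else:
            raise RuntimeError("metric undefined on every bootstrap resample")
        values[b] = value
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(values, [alpha, 1.0 - alpha])
    return ConfidenceInterval(float(lower), float(upper), "bootstrap_percentile", level, redraws)


def wilson_ci(successes: int, n: int, level: float = 0.95) -> ConfidenceInterval:
    """Closed-form Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes must lie in [0, {n}], got {successes}")
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    p = successes / n
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    # at p = 0 (p = 1) the closed form gives exactly 0 (1); avoid fp residue
    lower = 0.0 if successes == 0 else float(np.clip(center - half, 0.0, 1.0))
    upper = 1.0 if successes == n else float(np.clip(center + half, 0.0, 1.0))
    return ConfidenceInterval(lower, upper, "wilson", level)


def hanley_mcneil_ci(
    auc: float, n_pos: int, n_neg: int, level: float = 0.95
) -> ConfidenceInterval:
    """Hanley–McNeil normal-approximation CI for an AUC.

    SE² = [A(1−A) + (n⁺−1)(Q1−A²) + (n⁻−1)(Q2−A²)] / (n⁺ n⁻) with
    Q1 = A/(2−A), Q2 = 2A²/(1+A); the interval is clipped to [0, 1].
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError(f"auc must be in [0, 1], got {auc}")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("both groups must be non-empty")
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(1.0 - (1.0 - level) / 2.0)
    return ConfidenceInterval(
        float(np.clip(auc - z * se, 0.0, 1.0)),
        float(np.clip(auc + z * se, 0.0, 1.0)),
        "hanley_mcneil",
        level,
    )


def learning_curve(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    sizes: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    validation_fraction: float = 0.2,
) -> pd.DataFrame:
    """Train/validation accuracy as a function of training-set size.

    For each fold a stratified validation split is held out; for each
    size the first ``size`` training cases are fitted and scored on both
    their own training subset and the held-out split.  Returns a table of
    mean ± sd per size (sd is zero with one fold).  Sizes smaller than
    the number of classes are skipped with a warning.
    """
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ValueError("sizes must be increasing")
    X = np.asarray(X)
    y = np.asarray(y)
    n_classes = len(np.unique(y))
    rows = []
    splitter = StratifiedShuffleSplit(
        n_splits=folds, test_size=validation_fraction, random_state=seed
    )
    fold_results: dict[int, list[tuple[float, float]]] = {s: [] for s in sizes}
    for train_idx, val_idx in splitter.split(X, y):
        rng = np.random.default_rng(seed)
        order = train_idx.copy()
        rng.shuffle(order)
        for size in sizes:
            if size < n_classes:
                continue
            if size > len(order):
                raise ValueError(f"size {size} exceeds available training n {len(order)}")
            sub = order[:size]
            if len(np.unique(y[sub])) < 2:
                continue
            model = clone(estimator)
            model.fit(X[sub], y[sub])
            train_acc = float(np.mean(model.predict(X[sub]) == y[sub]))
            val_acc = float(np.mean(model.predict(X[val_idx]) == y[val_idx]))
            fold_results[size].append((train_acc, val_acc))
    for size in sizes:
        if size < n_classes:
            warnings.warn(
                f"size {size} < number of classes {n_classes}; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        results = fold_results[size]
        if not results:
            continue
        arr = np.asarray(results)
        rows.append(
            {
                "size": size,
                "train_accuracy_mean": arr[:, 0].mean(),
                "train_accuracy_sd": arr[:, 0].std(ddof=0),
                "validation_accuracy_mean": arr[:, 1].mean(),
                "validation_accuracy_sd": arr[:, 1].std(ddof=0),
                "folds": len(results),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Full evaluation of one fitted model on a held-out partition."""

    model: str
    n: int
    metrics: dict
    intervals: dict[str, ConfidenceInterval]
    confusion_matrix: np.ndarray
    class_names: tuple[str, ...]
    per_class_auc: dict[str, float]
    mean_auc: float
    mean_auc_weighted: float
    roc_curves: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "n": self.n,
            **{k: v for k, v in self.metrics.items() if k != "support"},
            "mean_auc": self.mean_auc,
            "mean_auc_weighted": self.mean_auc_weighted,
            "per_class_auc": self.per_class_auc,
            "confusion_matrix": self.confusion_matrix.tolist(),
            "class_order": list(self.class_names),
            "intervals": {
                name: {
                    "lower": ci.lower,
                    "upper": ci.upper,
                    "method": ci.method,
                    "level": ci.level,
                }
                for name, ci in self.intervals.items()
            },
        }


def _model_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))
    return np.asarray(model.decision_function(X))


def evaluate_model(
    model,
    model_name: str,
    X: np.ndarray,
    y,
    class_names: Sequence[str] = CATEGORIES,
    B: int = 1000,
    seed: int = 0,
) -> EvalReport:
    """Evaluate a fitted classifier: metrics, CIs, confusion matrix, ROC set.

    Labels may be integer codes into ``class_names`` or the names
    themselves.  Accuracy and per-class accuracies get Wilson intervals,
    the mean AUC a Hanley–McNeil interval (positives pooled over classes
    for the group sizes) — and accuracy, F1 and mean AUC additionally get
    seeded percentile-bootstrap intervals.
    """
    y = np.asarray(y)
    if y.dtype.kind in "iu":
        codes = y
    else:
        codes = _as_codes(y, list(class_names))
    label_codes = list(range(len(class_names)))
    y_pred = np.asarray(model.predict(X))

    metrics = multiclass_metrics(codes, y_pred, labels=label_codes)
    metrics["per_class_accuracy"] = {
        class_names[int(k)]: v for k, v in metrics["per_class_accuracy"].items()
    }
    support = {class_names[int(k)]: v for k, v in metrics["support"].items()}
    metrics["support"] = support
    matrix = confusion(codes, y_pred, labels=label_codes)

    scores = _model_scores(model, X)
    present = [i for i in label_codes if 0 < (codes == i).sum() < len(codes)]
    roc = roc_ovr(codes, scores, labels=label_codes)
    roc_w = roc_ovr(codes, scores, labels=label_codes, weighted=True)
    per_class_auc = {
        class_names[int(k)]: v for k, v in roc["per_class_auc"].items()
    }

    curves: dict[str, dict[str, np.ndarray]] = {}
    for i in present:
        fpr, tpr, _ = roc_curve(codes == i, scores[:, i])
        curves[class_names[i]] = {"fpr": fpr, "tpr": tpr}

    n = len(codes)
    correct = int(np.trace(matrix))
    intervals: dict[str, ConfidenceInterval] = {
        "accuracy_wilson": wilson_ci(correct, n),
        "accuracy_bootstrap": bootstrap_ci(
            lambda t, p: float(np.mean(t == p)), codes, y_pred, B=B, seed=seed
        ),
        "f1_weighted_bootstrap": bootstrap_ci(
            lambda t, p: multiclass_metrics(t, p, labels=label_codes)["f1_weighted"],
            codes,
            y_pred,
            B=B,
            seed=seed,
        ),
    }
    for i in label_codes:
        row = matrix[i].sum()
        if row > 0:
            intervals[f"per_class_accuracy_{class_names[i]}_wilson"] = wilson_ci(
                int(matrix[i, i]), int(row)
            )
    n_pos_mean = int(np.mean([(codes == i).sum() for i in present]))
    intervals["mean_auc_hanley_mcneil"] = hanley_mcneil_ci(
        min(max(roc["mean_auc"], 0.0), 1.0), max(n_pos_mean, 1), max(n - n_pos_mean, 1)
    )
    intervals["mean_auc_bootstrap"] = bootstrap_ci(
        lambda t, s: roc_ovr(t, s, labels=label_codes)["mean_auc"],
        codes,
        scores,
        B=B,
        seed=seed,
    )

    return EvalReport(
        model=model_name,
        n=n,
        metrics=metrics,
        intervals=intervals,
        confusion_matrix=matrix,
        class_names=tuple(class_names),
        per_class_auc=per_class_auc,
        mean_auc=roc["mean_auc"],
        mean_auc_weighted=roc_w["mean_auc"],
        roc_curves=curves,
    )
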