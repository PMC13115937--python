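"""Model harness: stratified partitioning, rule-augmented features, the
five-classifier bench, and the self-healing refinement loop.

The screening framework trains five conventional classifiers — gradient
boosting, logistic regression, random forest, SVM and XGBoost — on a
feature matrix that appends the rule engine's outputs (a weighted one-hot
of the five guideline categories plus the structural risk flag) to the
z-scored biometrics.  The rule block is the "instruction" channel: with a
positive weight, guideline boundaries are directly visible to the learner
instead of having to be rediscovered from raw biometry.

A refinement loop monitors validation accuracy for up to
``max_refinement_cycles`` cycles.  If accuracy falls more than 20%
(relative) below the best seen so far, the self-healing action for that
algorithm fires: random forests grow more/deeper trees, boosting models
halve their learning rate, logistic regression doubles its iteration cap,
and SVMs double C; the model is then refitted.  Estimators are only
refitted when a corrective action has changed their hyperparameters —
cycles are otherwise monitoring steps (optionally on bootstrap-resampled
validation data, which makes the monitored series stochastic).
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .preprocess import ScalerState, apply_scaler, fit_scaler
from .references import ReferenceTables, build_reference_tables
from .rules import (
    CATEGORIES,
    RuleEngine,
    al_deviation_pct,
    cr_deviation_pct,
    evaluate_rules,
    rule_features,
)
from .records import frame_to_records

__all__ = [
    "ALGORITHMS",
    "CONTINUOUS_FEATURES",
    "SplitSpec",
    "ModelSpec",
    "SelfHealEvent",
    "TrainResult",
    "stratified_split",
    "RuleFeatureBuilder",
    "build_feature_matrix",
    "default_specs",
    "make_estimator",
    "train_all",
    "self_heal",
]

ALGORITHMS = ("gradient_boosting", "logistic_regression", "random_forest", "svm", "xgboost")

#: Continuous inputs that are z-scored with the train-fitted scaler.
CONTINUOUS_FEATURES = (
    "age",
    "acuity_logmar",
    "se_d",
    "al_mm",
    "cr_mm",
    "al_cr",
    "al_dev_pct",
    "cr_dev_pct",
)

SELF_HEAL_THRESHOLD = 0.20  # relative validation-accuracy drop


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation/test partition specification."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    stratify_on: str = "category"
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {self.fractions}")


def stratified_split(
    frame: pd.DataFrame, spec: SplitSpec | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split a labeled cohort into disjoint, exhaustive 70/15/15 partitions.

    Rows are allocated class-by-class (largest-remainder rounding within
    each class), so per-class proportions in every partition track the
    overall mixture as closely as the counts permit.  Deterministic under
    ``spec.seed``.
    """
    spec = spec or SplitSpec()
    if len(frame) < 20:
        raise ValueError(f"need at least 20 subjects to split, got {len(frame)}")
    if spec.stratify_on not in frame.columns:
        raise ValueError(f"stratification column {spec.stratify_on!r} missing")
    rng = np.random.default_rng(spec.seed)
    parts: list[list[np.ndarray]] = [[], [], []]
    for _, group in frame.groupby(spec.stratify_on, sort=True):
        idx = group.index.to_numpy().copy()
        if len(idx) < 3:
            warnings.warn(
                f"class with {len(idx)} member(s) cannot appear in every "
                "partition; best-effort allocation",
                UserWarning,
                stacklevel=2,
            )
        rng.shuffle(idx)
        raw = np.asarray(spec.fractions) * len(idx)
        counts = np.floor(raw).astype(int)
        counts[np.argsort(-(raw - counts))[: len(idx) - counts.sum()]] += 1
        stops = np.cumsum(counts)
        parts[0].append(idx[: stops[0]])
        parts[1].append(idx[stops[0] : stops[1]])
        parts[2].append(idx[stops[1] : stops[2]])
    out = tuple(
        frame.loc[np.concatenate(p)].sort_index() if p else frame.iloc[0:0]
        for p in parts
    )
    return out  # type: ignore[return-value]


class RuleFeatureBuilder:
    """Build the 15-column feature matrix with a train-fitted scaler.

    Columns: 8 z-scored continuous features (age, acuity, SE, AL, CR,
    AL/CR, AL and CR percent deviation from the age reference means),
    the sex code, and the 6 weighted rule features.  The scaler must be
    fitted on the training partition before any transform.
    """

    def __init__(
        self,
        tables: ReferenceTables | None = None,
        mode: str = "non_cycloplegic",
        rule_weight: float = 1.0,
    ) -> None:
        self.tables = tables or build_reference_tables()
        self.mode = mode
        self.rule_weight = rule_weight
        self.scaler: ScalerState | None = None
        self.feature_names = (
            list(CONTINUOUS_FEATURES)
            + ["sex"]
            + [f"rule_{c.lower().replace(' ', '_').replace('-', '_')}" for c in CATEGORIES]
            + ["rule_risk_flag"]
        )

    def _augment(self, frame: pd.DataFrame) -> pd.DataFrame:
        out = frame.copy()
        out["al_cr"] = out["al_mm"] / out["cr_mm"]
        out["al_dev_pct"] = [
            al_deviation_pct(a, al, self.tables) for a, al in zip(out["age"], out["al_mm"])
        ]
        out["cr_dev_pct"] = [
            cr_deviation_pct(a, cr, self.tables) for a, cr in zip(out["age"], out["cr_mm"])
        ]
        return out

    def fit(self, train: pd.DataFrame) -> "RuleFeatureBuilder":
        augmented = self._augment(train)
        self.scaler = fit_scaler(augmented, CONTINUOUS_FEATURES)
        return self

    def transform(self, frame: pd.DataFrame) -> np.ndarray:
        if self.scaler is None:
            raise RuntimeError("builder not fitted; call fit() on the training partition")
        augmented = apply_scaler(self.scaler, self._augment(frame))
        continuous = augmented[list(CONTINUOUS_FEATURES)].to_numpy(dtype=float)
        sex = frame["sex"].to_numpy(dtype=float)[:, None]
        rules = np.vstack(
            [
                rule_features(evaluate_rules(r, self.tables, self.mode), self.rule_weight)
                for r in frame_to_records(frame)
            ]
        )
        return np.hstack([continuous, sex, rules])

    def labels(self, frame: pd.DataFrame) -> np.ndarray:
        """Integer class codes (0..4 in the canonical category order)."""
        return np.array([CATEGORIES.index(c) for c in frame["category"]])


def build_feature_matrix(
    cohort: pd.DataFrame,
    tables: ReferenceTables | None = None,
    mode: str = "non_cycloplegic",
    rule_feature_weight: float = 1.0,
    train: pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """One-shot feature matrix: returns (X, y, feature_names).

    ``train`` designates the partition the scaler is fitted on (defaults
    to ``cohort`` itself).
    """
    builder = RuleFeatureBuilder(tables, mode, rule_feature_weight)
    builder.fit(cohort if train is None else train)
    X = builder.transform(cohort)
    y = builder.labels(cohort) if "category" in cohort.columns else np.array([])
    return X, y, builder.feature_names


@dataclass(frozen=True)
class ModelSpec:
    """One classifier's configuration in the five-algorithm bench."""

    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    rule_feature_weight: float = 1.0
    max_refinement_cycles: int = 50

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")


def default_specs(rule_feature_weight: float = 1.0, max_refinement_cycles: int = 50) -> list[ModelSpec]:
    """The five-algorithm bench with mainstream library defaults.

    Random forest carries an explicit depth cap so the self-healing
    "deepen the trees" action is meaningful.
    """
    defaults: dict[str, dict[str, object]] = {
        "gradient_boosting": {"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3},
        "logistic_regression": {"max_iter": 1000, "C": 1.0},
        "random_forest": {"n_estimators": 100, "max_depth": 10},
        "svm": {"C": 1.0, "kernel": "rbf", "gamma": "scale"},
        "xgboost": {"n_estimators": 100, "learning_rate": 0.3, "max_depth": 6},
    }
    return [
        ModelSpec(
            algorithm=name,
            hyperparameters=defaults[name],
            rule_feature_weight=rule_feature_weight,
            max_refinement_cycles=max_refinement_cycles,
        )
        for name in ALGORITHMS
    ]


def make_estimator(spec: ModelSpec, seed: int = 0):
    """Instantiate the scikit-learn / XGBoost estimator behind a spec."""
    params = dict(spec.hyperparameters)
    if spec.algorithm == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if spec.algorithm == "logistic_regression":
        return LogisticRegression(random_state=seed, **params)
    if spec.algorithm == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if spec.algorithm == "svm":
        return SVC(random_state=seed, decision_function_shape="ovr", **params)
    if spec.algorithm == "xgboost":
        return XGBClassifier(random_state=seed, verbosity=0, **params)
    raise ValueError(f"unknown algorithm {spec.algorithm!r}")  # pragma: no cover


@dataclass(frozen=True)
class SelfHealEvent:
    """Record of one self-healing activation."""

    algorithm: str
    cycle: int
    previous_best: float
    current: float
    relative_drop: float
    action: str


def self_heal(
    spec: ModelSpec, previous_best: float | None, current: float, cycle: int = 0
) -> tuple[ModelSpec, SelfHealEvent | None]:
    """Apply the per-algorithm corrective action if the trigger condition holds.

    The trigger is a relative validation-accuracy drop of more than 20%
    versus the best accuracy observed so far.  Without a prior best the
    call is a no-op (returns the spec unchanged and no event).
    """
    if previous_best is None or previous_best <= 0:
        return spec, None
    drop = (previous_best - current) / previous_best
    if drop <= SELF_HEAL_THRESHOLD:
        return spec, None
    params = dict(spec.hyperparameters)
    if spec.algorithm == "random_forest":
        params["n_estimators"] = int(params.get("n_estimators", 100)) * 2
        depth = params.get("max_depth")
        params["max_depth"] = (int(depth) + 2) if depth is not None else None
        action = "n_estimators x2, max_depth +2"
    elif spec.algorithm in ("gradient_boosting", "xgboost"):
        params["learning_rate"] = float(params.get("learning_rate", 0.1)) * 0.5
        action = "learning_rate x0.5"
    elif spec.algorithm == "logistic_regression":
        params["max_iter"] = int(params.get("max_iter", 100)) * 2
        action = "max_iter x2"
    else:  # svm
        params["C"] = float(params.get("C", 1.0)) * 2.0
        action = "C x2"
    event = SelfHealEvent(
        algorithm=spec.algorithm,
        cycle=cycle,
        previous_best=previous_best,
        current=current,
        relative_drop=drop,
        action=action,
    )
    return replace(spec, hyperparameters=params), event


@dataclass
class TrainResult:
    """Fitted bench: estimators, final specs, refinement log and the builder."""

    models: dict[str, object]
    specs: dict[str, ModelSpec]
    refinement_log: list[dict]
    heal_events: list[SelfHealEvent]
    builder: RuleFeatureBuilder
    train_accuracy: dict[str, float]
    validation_accuracy: dict[str, float]
    fit_seconds: dict[str, float]


def train_all(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    specs: Sequence[ModelSpec] | None = None,
    tables: ReferenceTables | None = None,
    mode: str = "non_cycloplegic",
    seed: int = 0,
    resample_validation: bool = False,
) -> TrainResult:
    """Fit the bench with refinement-loop monitoring and self-healing.

    Each model is fitted on the training partition, then monitored for
    ``max_refinement_cycles`` cycles on the validation partition (each
    cycle's accuracy is logged).  With ``resample_validation`` the monitor
    evaluates on a seeded bootstrap resample of the validation set each
    cycle, making the series stochastic; otherwise the full validation
    set is used.  A >20% relative drop versus the running best triggers
    the corrective action and a refit.
    """
    specs = list(specs) if specs is not None else default_specs()
    if "category" not in train.columns:
        raise ValueError("training partition must carry a 'category' label column")
    if train["category"].nunique() < 2:
        raise ValueError("training partition is single-class; cannot fit classifiers")

    result_models: dict[str, object] = {}
    result_specs: dict[str, ModelSpec] = {}
    log: list[dict] = []
    heal_events: list[SelfHealEvent] = []
    train_acc: dict[str, float] = {}
    val_acc: dict[str, float] = {}
    fit_seconds: dict[str, float] = {}
    shared_builder: RuleFeatureBuilder | None = None
    rng = np.random.default_rng(seed)

    for spec in specs:
        builder = RuleFeatureBuilder(tables, mode, spec.rule_feature_weight)
        builder.fit(train)
        if shared_builder is None:
            shared_builder = builder
        X_train, y_train = builder.transform(train), builder.labels(train)
        X_val, y_val = builder.transform(validation), builder.labels(validation)

        current_spec = spec
        model = make_estimator(current_spec, seed)
        t0 = time.perf_counter()
        model.fit(X_train, y_train)
        elapsed = time.perf_counter() - t0

        best: float | None = None
        for cycle in range(max(1, spec.max_refinement_cycles)):
            if resample_validation and len(y_val) > 0:
                idx = rng.integers(0, len(y_val), size=len(y_val))
                acc = float(np.mean(model.predict(X_val[idx]) == y_val[idx]))
            else:
                acc = float(np.mean(model.predict(X_val) == y_val))
            entry = {
                "model": spec.algorithm,
                "cycle": cycle,
                "validation_accuracy": acc,
                "action": None,
            }
            healed_spec, event = self_heal(current_spec, best, acc, cycle)
            if event is not None:
                current_spec = healed_spec
                heal_events.append(event)
                entry["action"] = event.action
                model = make_estimator(current_spec, seed)
                t0 = time.perf_counter()
                model.fit(X_train, y_train)
                elapsed += time.perf_counter() - t0
            best = acc if best is None else max(best, acc)
            log.append(entry)

        result_models[spec.algorithm] = model
        result_specs[spec.algorithm] = current_spec
        train_acc[spec.algorithm] = float(np.mean(model.predict(X_train) == y_train))
        val_acc[spec.algorithm] = float(np.mean(model.predict(X_val) == y_val))
        fit_seconds[spec.algorithm] = elapsed

    assert shared_builder is not None
    return TrainResult(
        models=result_models,
        specs=result_specs,
        refinement_log=log,
        heal_events=heal_events,
        builder=shared_builder,
        train_accuracy=train_acc,
        validation_accuracy=val_acc,
        fit_seconds=fit_seconds,
    )
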