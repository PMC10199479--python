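"""Classifier pipelines, nested cross-validation, and evaluation metrics.

Two algorithm families are supported over an identical preprocessing stack
(degree-2 polynomial feature expansion followed by min/max scaling to
[0, 1]): support vector machines (linear or RBF kernel) and random forests.
Model selection uses nested cross-validation — 20 independent trials, each
re-shuffling the data with the trial index as random state, with stratified
4-fold outer and inner loops; the inner loop grid-searches hyperparameters
by accuracy, the outer loop scores the refitted winner on held-out folds.
Reported scores are means over all outer test folds of all trials, which
keeps hyperparameter selection from ever seeing the rows it is judged on.

The shipped final configuration is a 1500-tree random forest (entropy
criterion, depth 30, min 3 samples per leaf, sqrt max-features) trained on
the entire labelled table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from collections import Counter
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler, PolynomialFeatures
from sklearn.svm import SVC
from sklearn.utils import shuffle as _shuffle

from .dataset import FeatureTable
from .errors import SchemaMismatchError, ValidationError

logger = logging.getLogger(__name__)

ALGORITHMS = ("svm", "rf")

#: Positive class label (depolymerase).
POSITIVE_CLASS = 1

_SVM_KEYS = {"kernel", "C", "gamma"}
_RF_KEYS = {
    "n_estimators",
    "max_depth",
    "min_samples_leaf",
    "min_samples_split",
    "max_features",
    "criterion",
}


@dataclass(frozen=True)
class ModelConfig:
    """Algorithm choice, preprocessing order, hyperparameters, and seed."""

    algorithm: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    preprocessing: tuple[str, ...] = ("polynomial", "minmax")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValidationError(
                f"algorithm must be one of {ALGORITHMS}, got '{self.algorithm}'"
            )
        allowed = _SVM_KEYS if self.algorithm == "svm" else _RF_KEYS
        extra = set(self.hyperparameters) - allowed
        if extra:
            raise ValidationError(
                f"hyperparameters {sorted(extra)} are not valid for "
                f"algorithm '{self.algorithm}'"
            )
        unknown = set(self.preprocessing) - {"polynomial", "minmax"}
        if unknown:
            raise ValidationError(f"unknown preprocessing steps {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            algorithm=payload["algorithm"],
            hyperparameters=payload.get("hyperparameters", {}),
            preprocessing=tuple(payload.get("preprocessing", ("polynomial", "minmax"))),
            seed=int(payload.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "preprocessing": list(self.preprocessing),
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }


def final_rf_config() -> ModelConfig:
    """The shipped final random-forest configuration (bundled JSON)."""
    with resources.files("depp").joinpath("data/final_rf.json").open() as fh:
        payload = json.load(fh)
    return ModelConfig(
        algorithm=payload["algorithm"],
        hyperparameters=payload["hyperparameters"],
        preprocessing=tuple(payload["preprocessing"]),
        seed=int(payload["seed"]),
    )


def load_grid(algorithm: str, breadth: str = "reduced") -> list[dict]:
    """A bundled hyperparameter grid (``full`` or ``reduced`` breadth)."""
    with resources.files("depp").joinpath("data/default_grids.json").open() as fh:
        grids = json.load(fh)
    try:
        return grids[algorithm][breadth]
    except KeyError:
        raise ValidationError(
            f"no bundled grid for algorithm='{algorithm}', breadth='{breadth}'"
        ) from None


def build_pipeline(config: ModelConfig, random_state: int | None = None) -> Pipeline:
    """Assemble the preprocessing + classifier pipeline for a configuration.

    ``random_state`` overrides ``config.seed`` (used by the nested-CV harness
    to seed each trial with its trial index).
    """
    seed = config.seed if random_state is None else random_state
    steps = []
    for step in config.preprocessing:
        if step == "polynomial":
            steps.append(
                ("polynomial", PolynomialFeatures(degree=2, include_bias=False))
            )
        elif step == "minmax":
            steps.append(("minmax", MinMaxScaler()))
    hp = dict(config.hyperparameters)
    if config.algorithm == "svm":
        clf = SVC(
            kernel=hp.get("kernel", "linear"),
            C=float(hp.get("C", 1.0)),
            gamma=hp.get("gamma", "scale"),
            random_state=seed,
        )
    else:
        clf = RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 100)),
            max_depth=hp.get("max_depth"),
            min_samples_leaf=int(hp.get("min_samples_leaf", 1)),
            min_samples_split=int(hp.get("min_samples_split", 2)),
            max_features=hp.get("max_features", "sqrt"),
            criterion=hp.get("criterion", "entropy"),
            random_state=seed,
            n_jobs=1,
        )
    steps.append(("clf", clf))
    return Pipeline(steps)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class EvaluationMetrics:
    """Confusion counts with the derived accuracy and recall.

    ``accuracy = (TP + TN) / (TP + FP + TN + FN)`` and
    ``recall = TP / (TP + FN)``; recall is ``None`` (missing, not 0) when no
    positive examples were evaluated. ``rates`` holds the row-normalized
    confusion matrix: tpr/fnr over actual positives, tnr/fpr over actual
    negatives.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    recall: float | None
    rates: Mapping[str, float | None]

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> EvaluationMetrics:
    """Derive accuracy, recall, and per-class rates from confusion counts."""
    counts = dict(tp=tp, fp=fp, tn=tn, fn=fn)
    for name, value in counts.items():
        if value < 0:
            raise ValidationError(f"{name} must be >= 0, got {value}")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValidationError("confusion counts sum to zero")
    accuracy = (tp + tn) / total
    pos = tp + fn
    neg = tn + fp
    recall = tp / pos if pos else None
    rates = {
        "tpr": tp / pos if pos else None,
        "fnr": fn / pos if pos else None,
        "tnr": tn / neg if neg else None,
        "fpr": fp / neg if neg else None,
    }
    return EvaluationMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy, recall=recall, rates=rates
    )


def metrics_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> EvaluationMetrics:
    """Confusion counts (positive class = 1) from labelled predictions."""
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    return compute_metrics(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class NestedCVResult:
    """Per-fold and aggregate outcomes of a nested cross-validation run."""

    algorithm: str
    n_trials: int
    n_splits: int
    fold_metrics: list[EvaluationMetrics]
    best_params_per_fold: list[dict]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.accuracy for m in self.fold_metrics]))

    @property
    def mean_recall(self) -> float | None:
        vals = [m.recall for m in self.fold_metrics if m.recall is not None]
        return float(np.mean(vals)) if vals else None

    @property
    def aggregate(self) -> EvaluationMetrics:
        """Metrics over the summed confusion counts of all outer folds."""
        return compute_metrics(
            tp=sum(m.tp for m in self.fold_metrics),
            fp=sum(m.fp for m in self.fold_metrics),
            tn=sum(m.tn for m in self.fold_metrics),
            fn=sum(m.fn for m in self.fold_metrics),
        )

    @property
    def modal_params(self) -> dict:
        """The most frequently selected hyperparameter configuration."""
        if not self.best_params_per_fold:
            return {}
        keyed = Counter(
            tuple(sorted(p.items())) for p in self.best_params_per_fold
        )
        return dict(keyed.most_common(1)[0][0])

    def to_dict(self) -> dict:
        agg = self.aggregate
        return {
            "algorithm": self.algorithm,
            "n_trials": self.n_trials,
            "n_splits": self.n_splits,
            "mean_accuracy": self.mean_accuracy,
            "mean_recall": self.mean_recall,
            "aggregate_counts": {
                "tp": agg.tp, "fp": agg.fp, "tn": agg.tn, "fn": agg.fn
            },
            "normalized_confusion": dict(agg.rates),
            "modal_params": self.modal_params,
            "fold_accuracies": [m.accuracy for m in self.fold_metrics],
            "fold_recalls": [m.recall for m in self.fold_metrics],
        }


def _check_cv_feasible(y: np.ndarray, n_splits: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("both classes must be present for cross-validation")
    if counts.min() < n_splits:
        raise ValidationError(
            f"smallest class has {counts.min()} rows, fewer than n_splits="
            f"{n_splits}; provide more data or fewer splits"
        )


def nested_cv_evaluate(
    table: FeatureTable,
    algorithm: str,
    grid: Sequence[Mapping] | Mapping | None = None,
    n_trials: int = 20,
    n_splits: int = 4,
    base_config: ModelConfig | None = None,
) -> NestedCVResult:
    """Estimate generalization performance with nested cross-validation.

    For each trial ``t`` in ``0..n_trials-1`` the rows are shuffled with
    random state ``t`` (the trial index also seeds the classifier); a
    stratified ``n_splits``-fold outer loop holds out each fold in turn,
    while an inner stratified ``n_splits``-fold grid search over ``grid``
    picks the accuracy-maximizing hyperparameters on the outer training
    fold only (ties broken by enumeration order). The winner is refit on
    the outer training fold and scored on the held-out fold.

    ``grid`` is a scikit-learn style parameter grid over classifier
    hyperparameters (a dict of lists, or a list of such dicts). ``None`` or
    a single-point grid skips the inner search and evaluates the fixed
    configuration in ``base_config``.
    """
    if algorithm not in ALGORITHMS:
        raise ValidationError(f"algorithm must be one of {ALGORITHMS}")
    if not table.is_labelled:
        raise ValidationError("nested CV requires a labelled table")
    if base_config is None:
        base_config = ModelConfig(algorithm=algorithm)
    elif base_config.algorithm != algorithm:
        raise ValidationError("base_config.algorithm disagrees with `algorithm`")

    X = table.features.to_numpy(dtype=float)
    y = table.labels.to_numpy()
    _check_cv_feasible(y, n_splits)

    if grid is not None and isinstance(grid, Mapping):
        grid = [dict(grid)]
    search_space = None
    if grid:
        n_points = sum(
            int(np.prod([len(v) for v in g.values()])) if g else 1 for g in grid
        )
        if n_points > 1:
            search_space = [
                {f"clf__{k}": list(v) for k, v in g.items()} for g in grid
            ]
        else:  # single-point grid: fold it into the fixed configuration
            merged = dict(base_config.hyperparameters)
            merged.update({k: v[0] for k, v in grid[0].items()})
            base_config = ModelConfig(
                algorithm=algorithm,
                hyperparameters=merged,
                preprocessing=base_config.preprocessing,
                seed=base_config.seed,
            )

    fold_metrics: list[EvaluationMetrics] = []
    best_params: list[dict] = []
    for trial in range(n_trials):
        X_t, y_t = _shuffle(X, y, random_state=trial)
        outer = StratifiedKFold(n_splits=n_splits, shuffle=False)
        for train_idx, test_idx in outer.split(X_t, y_t):
            pipeline = build_pipeline(base_config, random_state=trial)
            if search_space is not None:
                inner = StratifiedKFold(n_splits=n_splits, shuffle=False)
                search = GridSearchCV(
                    pipeline,
                    search_space,
                    scoring="accuracy",
                    cv=inner,
                    n_jobs=1,
                    refit=True,
                )
                search.fit(X_t[train_idx], y_t[train_idx])
                fitted = search.best_estimator_
                best_params.append(
                    {k.removeprefix("clf__"): v for k, v in search.best_params_.items()}
                )
            else:
                fitted = pipeline.fit(X_t[train_idx], y_t[train_idx])
                best_params.append(dict(base_config.hyperparameters))
            y_pred = fitted.predict(X_t[test_idx])
            fold_metrics.append(metrics_from_predictions(y_t[test_idx], y_pred))
    return NestedCVResult(
        algorithm=algorithm,
        n_trials=n_trials,
        n_splits=n_splits,
        fold_metrics=fold_metrics,
        best_params_per_fold=best_params,
    )


# ---------------------------------------------------------------------------
# final model


@dataclass
class TrainedModel:
    """A fitted pipeline bound to its feature schema and provenance.

    Predictions are refused on tables whose column names or order differ
    from the columns the model was trained on.
    """

    pipeline: Pipeline
    feature_names: tuple[str, ...]
    config: ModelConfig
    training_hash: str
    version: str = "1"

    def _check_schema(self, columns: Sequence[str]) -> None:
        columns = tuple(str(c) for c in columns)
        if columns != self.feature_names:
            for i, (got, want) in enumerate(zip(columns, self.feature_names)):
                if got != want:
                    raise SchemaMismatchError(
                        f"feature column {i} is '{got}' but the model was "
                        f"trained on '{want}'"
                    )
            raise SchemaMismatchError(
                f"expected {len(self.feature_names)} feature columns, "
                f"got {len(columns)}"
            )

    def predict_proba(self, table: FeatureTable | pd.DataFrame) -> np.ndarray:
        """P(depolymerase) for each row, order-aligned with the input.

        For the random forest this is the fraction of trees voting for the
        positive class, after the pipeline's preprocessing.
        """
        features = table.features if isinstance(table, FeatureTable) else table
        self._check_schema(features.columns)
        if len(features) == 0:
            return np.empty(0, dtype=float)
        proba = self.pipeline.predict_proba(features.to_numpy(dtype=float))
        positive_col = list(self.pipeline.classes_).index(POSITIVE_CLASS)
        return proba[:, positive_col]

    def predict(self, table: FeatureTable | pd.DataFrame) -> np.ndarray:
        features = table.features if isinstance(table, FeatureTable) else table
        self._check_schema(features.columns)
        if len(features) == 0:
            return np.empty(0, dtype=int)
        return self.pipeline.predict(features.to_numpy(dtype=float)).astype(int)

    def save(self, path: str | Path) -> None:
        joblib.dump(
            {
                "pipeline": self.pipeline,
                "feature_names": self.feature_names,
                "config": self.config.to_dict(),
                "training_hash": self.training_hash,
                "version": self.version,
            },
            path,
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = joblib.load(path)
        cfg = payload["config"]
        return cls(
            pipeline=payload["pipeline"],
            feature_names=tuple(payload["feature_names"]),
            config=ModelConfig(
                algorithm=cfg["algorithm"],
                hyperparameters=cfg["hyperparameters"],
                preprocessing=tuple(cfg["preprocessing"]),
                seed=cfg["seed"],
            ),
            training_hash=payload["training_hash"],
            version=payload.get("version", "1"),
        )


def table_fingerprint(table: FeatureTable) -> str:
    """SHA-256 over the table's ids, columns, values, and labels."""
    digest = hashlib.sha256()
    digest.update("\x00".join(table.ids).encode())
    digest.update("\x00".join(table.feature_names).encode())
    digest.update(np.ascontiguousarray(table.features.to_numpy(float)).tobytes())
    if table.labels is not None:
        digest.update(table.labels.to_numpy().tobytes())
    return digest.hexdigest()


def train_final_model(
    table: FeatureTable, config: ModelConfig | None = None
) -> TrainedModel:
    """Fit the full pipeline on the entire labelled table.

    Default configuration is the shipped 1500-tree random forest.
    Deterministic given ``config.seed``; the returned model can be saved
    and reloaded with bit-identical predictions.
    """
    if config is None:
        config = final_rf_config()
    if not table.is_labelled:
        raise ValidationError("training requires a labelled table")
    y = table.labels.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("training table contains a single class")
    pipeline = build_pipeline(config)
    pipeline.fit(table.features.to_numpy(dtype=float), y)
    return TrainedModel(
        pipeline=pipeline,
        feature_names=table.feature_names,
        config=config,
        training_hash=table_fingerprint(table),
    )
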