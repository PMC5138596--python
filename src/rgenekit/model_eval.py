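"""Classifier training, prediction and the binary evaluation-metric suite.

The working classifier is a random forest (100 trees, sqrt(p) features per
split, unlimited depth, seedable); other common learners (SVM, naive Bayes,
k-NN, bagging, boosting) are reachable through the same ``LearnerSpec``
interface for comparison studies. Per-instance weights from the balancing
stage are honored by weight-aware fits.

Metrics follow the usual bioinformatics conventions for a positive class of
R-gene (resistance gene):

    SN  = TP / (TP + FN)                      sensitivity (fraction)
    SP  = TN / (TN + FP)                      specificity (fraction)
    Acc = 100 * (TP + TN) / m                 overall accuracy (percent)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

and ROC area is the rank-statistic (concordance) form, ties counted half,
which equals trapezoidal integration of the ROC curve.

Evaluation protocols: hold-out scoring of a fitted model, and stratified
10-fold cross-validation with fold predictions pooled into a single
confusion matrix before scoring (so one SN/SP/Acc/MCC per run, not a
fold mean).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from rgenekit.balancing import LabeledDataset

POSITIVE = 1
DECISION_THRESHOLD = 0.5


# ---------------------------------------------------------------- metrics

@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = R-gene."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def m(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def confusion(labels: np.ndarray, predictions: np.ndarray) -> ConfusionMatrix:
    """Tally a confusion matrix from 0/1 truth and 0/1 predictions."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have the same length")
    return ConfusionMatrix(
        tp=int(np.sum((labels == 1) & (predictions == 1))),
        fn=int(np.sum((labels == 1) & (predictions == 0))),
        tn=int(np.sum((labels == 0) & (predictions == 0))),
        fp=int(np.sum((labels == 0) & (predictions == 1))),
    )


def metric_sn_sp_acc(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy%); empty classes yield NaN + warning."""
    if cm.tp + cm.fn > 0:
        sn = cm.tp / (cm.tp + cm.fn)
    else:
        warnings.warn("no positive instances: SN undefined (NaN)", stacklevel=2)
        sn = math.nan
    if cm.tn + cm.fp > 0:
        sp = cm.tn / (cm.tn + cm.fp)
    else:
        warnings.warn("no negative instances: SP undefined (NaN)", stacklevel=2)
        sp = math.nan
    acc = 100.0 * (cm.tp + cm.tn) / cm.m if cm.m else math.nan
    return sn, sp, acc


def metric_mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient; 0 (with warning) when a marginal is empty."""
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        warnings.warn("a confusion-matrix marginal is zero: MCC reported as 0", stacklevel=2)
        return 0.0
    return (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)


def metric_roc_area(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC area as the rank statistic: P(score_pos > score_neg), ties half.

    Equivalent to the Mann-Whitney U statistic normalized by n_pos * n_neg.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC area requires both classes to be present")
    ranks = rankdata(scores)  # average ranks handle ties -> half credit
    rank_sum_pos = float(ranks[labels == 1].sum())
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


@dataclass
class EvalReport:
    """One evaluation protocol's outcome: counts plus summary metrics."""

    confusion: ConfusionMatrix
    sn: float
    sp: float
    acc: float
    mcc: float
    roc_area: float
    protocol: str  # holdout | cv10
    seed: int | None = None

    @classmethod
    def from_predictions(
        cls,
        labels: np.ndarray,
        scores: np.ndarray,
        protocol: str,
        seed: int | None = None,
    ) -> "EvalReport":
        preds = (np.asarray(scores) >= DECISION_THRESHOLD).astype(int)
        cm = confusion(labels, preds)
        sn, sp, acc = metric_sn_sp_acc(cm)
        labels = np.asarray(labels, dtype=int)
        both = (labels == 1).any() and (labels == 0).any()
        roc = metric_roc_area(labels, scores) if both else math.nan
        return cls(
            confusion=cm, sn=sn, sp=sp, acc=acc, mcc=metric_mcc(cm),
            roc_area=roc, protocol=protocol, seed=seed,
        )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["confusion"] = asdict(self.confusion)
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


# ------------------------------------------------------------- learners

@dataclass(frozen=True)
class LearnerSpec:
    """A named learner plus hyperparameter overrides."""

    name: str = "random_forest"
    params: tuple[tuple[str, Any], ...] = ()

    @classmethod
    def make(cls, name: str = "random_forest", **params: Any) -> "LearnerSpec":
        return cls(name=name, params=tuple(sorted(params.items())))


def make_learner(spec: LearnerSpec, seed: int | None = None):
    """Instantiate the scikit-learn estimator behind a spec."""
    params = dict(spec.params)
    builders = {
        "random_forest": lambda: RandomForestClassifier(
            n_estimators=100, max_features="sqrt", max_depth=None,
            random_state=seed, **params,
        ),
        "decision_tree": lambda: DecisionTreeClassifier(random_state=seed, **params),
        "naive_bayes": lambda: GaussianNB(**params),
        "knn": lambda: KNeighborsClassifier(**{"n_neighbors": 1, **params}),
        "svm": lambda: SVC(probability=True, random_state=seed, **params),
        "bagging": lambda: BaggingClassifier(random_state=seed, **params),
        "adaboost": lambda: AdaBoostClassifier(random_state=seed, **params),
        "gbdt": lambda: GradientBoostingClassifier(random_state=seed, **params),
    }
    try:
        return builders[spec.name]()
    except KeyError:
        raise ValueError(f"unknown learner {spec.name!r}; choose from {sorted(builders)}") from None


# -------------------------------------------------------- model artifact

@dataclass
class ModelArtifact:
    """A fitted model plus the feature schema it insists on at predict time."""

    estimator: Any
    feature_names: list[str]
    learner_spec: LearnerSpec
    seed: int | None
    dataset_hash: str

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(self.estimator, path)
        meta = {
            "feature_names": self.feature_names,
            "learner": self.learner_spec.name,
            "params": dict(self.learner_spec.params),
            "seed": self.seed,
            "dataset_hash": self.dataset_hash,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ModelArtifact":
        path = Path(path)
        estimator = joblib.load(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            estimator=estimator,
            feature_names=meta["feature_names"],
            learner_spec=LearnerSpec.make(meta["learner"], **meta["params"]),
            seed=meta["seed"],
            dataset_hash=meta["dataset_hash"],
        )


def _hash_dataset(dataset: LabeledDataset) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(dataset.features, index=True).to_numpy().tobytes())
    h.update(pd.util.hash_pandas_object(dataset.labels, index=True).to_numpy().tobytes())
    return h.hexdigest()[:16]


def _validate(dataset: LabeledDataset) -> None:
    if dataset.features.isna().any().any():
        raise ValueError("feature matrix contains NaN values")
    counts = dataset.class_counts()
    if len(counts) < 2:
        raise ValueError("training requires both classes")
    if min(counts.values()) < 2:
        raise ValueError("training requires at least 2 instances per class")


def train(
    train_set: LabeledDataset,
    learner_spec: LearnerSpec | None = None,
    seed: int | None = 0,
) -> ModelArtifact:
    """Fit a learner on a labeled dataset; honors per-instance weights."""
    spec = learner_spec or LearnerSpec()
    _validate(train_set)
    estimator = make_learner(spec, seed)
    X = train_set.features.to_numpy(dtype=float)
    y = train_set.y()
    if train_set.weights is not None:
        estimator.fit(X, y, sample_weight=train_set.weights.to_numpy(dtype=float))
    else:
        estimator.fit(X, y)
    return ModelArtifact(
        estimator=estimator,
        feature_names=list(train_set.features.columns),
        learner_spec=spec,
        seed=seed,
        dataset_hash=_hash_dataset(train_set),
    )


def _check_schema(model: ModelArtifact, features: pd.DataFrame) -> None:
    expected, got = list(model.feature_names), list(features.columns)
    if expected != got:
        missing = sorted(set(expected) - set(got))
        extra = sorted(set(got) - set(expected))
        raise ValueError(
            f"feature schema mismatch: missing columns {missing}, extra columns {extra}"
            if missing or extra
            else "feature schema mismatch: same columns in a different order"
        )


def predict(model: ModelArtifact, features: pd.DataFrame) -> pd.DataFrame:
    """Score records: positive-class probability plus label at threshold 0.5."""
    _check_schema(model, features)
    if len(features) == 0:
        return pd.DataFrame(columns=["score", "label"], index=features.index)
    scores = model.estimator.predict_proba(features.to_numpy(dtype=float))[:, POSITIVE]
    return pd.DataFrame(
        {"score": scores, "label": (scores >= DECISION_THRESHOLD).astype(int)},
        index=features.index,
    )


def evaluate_holdout(model: ModelArtifact, test_set: LabeledDataset, seed: int | None = None) -> EvalReport:
    """Score a fitted model on an untouched hold-out set."""
    preds = predict(model, test_set.features)
    return EvalReport.from_predictions(test_set.y(), preds["score"].to_numpy(), "holdout", seed)


def cross_validate(
    dataset: LabeledDataset,
    learner_spec: LearnerSpec | None = None,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold CV with fold predictions pooled, then scored once."""
    spec = learner_spec or LearnerSpec()
    _validate(dataset)
    counts = dataset.class_counts()
    if k > min(counts.values()):
        raise ValueError(f"k={k} exceeds the smallest class count {min(counts.values())}")

    X = dataset.features.to_numpy(dtype=float)
    y = dataset.y()
    w = dataset.weights.to_numpy(dtype=float) if dataset.weights is not None else None

    scores = np.empty(len(y))
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(X, y):
        estimator = clone(make_learner(spec, seed))
        if w is not None:
            estimator.fit(X[train_idx], y[train_idx], sample_weight=w[train_idx])
        else:
            estimator.fit(X[train_idx], y[train_idx])
        scores[test_idx] = estimator.predict_proba(X[test_idx])[:, POSITIVE]

    return EvalReport.from_predictions(y, scores, f"cv{k}", seed)
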