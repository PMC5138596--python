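"""Class-imbalance handling: random under-sampling and instance weighting.

Two strategies, matching common practice for two-class protein datasets where
negatives outnumber positives:

* ``under_sample``: down-sample the majority class uniformly without
  replacement to the minority size; the unsampled majority instances form a
  hold-out test set. With 6720 positives and 10028 negatives this yields a
  6720/6720 training set and a 3308-negative hold-out.
* ``weighted_sample``: keep every instance and attach per-instance weights,
  consumed by weight-aware learners (equivalently, a weighted bootstrap).
  "paper" mode uses class weights 10 (minority) and 7 (majority), which with
  a roughly 7:10 class ratio makes the total class masses near-equal; "auto"
  mode uses inverse class frequency normalized to mean weight 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from rgenekit.sequence_io import NEGATIVE_LABEL, POSITIVE_LABEL

PAPER_CLASS_WEIGHTS = {"minority": 10.0, "majority": 7.0}


@dataclass
class LabeledDataset:
    """A feature matrix with aligned binary labels and optional weights."""

    features: pd.DataFrame
    labels: pd.Series  # values in {POSITIVE_LABEL, NEGATIVE_LABEL}
    weights: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index):
            raise ValueError("features and labels must share the same index")
        if self.weights is not None and not self.features.index.equals(self.weights.index):
            raise ValueError("weights index must match features index")
        bad = set(self.labels.unique()) - {POSITIVE_LABEL, NEGATIVE_LABEL}
        if bad:
            raise ValueError(f"unexpected labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def ids(self) -> list[str]:
        return list(self.features.index)

    def class_counts(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()

    def subset(self, ids: pd.Index | list[str]) -> "LabeledDataset":
        w = self.weights.loc[ids] if self.weights is not None else None
        return LabeledDataset(self.features.loc[ids], self.labels.loc[ids], w)

    def y(self) -> np.ndarray:
        """Labels as 0/1 (positive class = 1)."""
        return (self.labels == POSITIVE_LABEL).to_numpy(dtype=int)


@dataclass
class SamplingPlan:
    """Record of a balancing decision, for provenance."""

    strategy: str  # none | under_sample | weighted
    seed: int | None = None
    class_weights: dict[str, float] | None = None
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)


def under_sample(dataset: LabeledDataset, seed: int) -> tuple[LabeledDataset, LabeledDataset]:
    """Balance by uniform random down-sampling of the majority class.

    Returns (train, holdout): the train set has equal per-class counts
    (minority size each); the holdout holds the unsampled majority
    instances. The minority class is never discarded. Deterministic per seed.
    """
    counts = dataset.class_counts()
    if len(counts) < 2:
        raise ValueError("under-sampling requires both classes to be present")
    minority_label = min(counts, key=lambda k: (counts[k], k))
    majority_label = next(k for k in counts if k != minority_label)

    rng = np.random.default_rng(seed)
    majority_ids = dataset.labels.index[dataset.labels == majority_label]
    keep = rng.choice(len(majority_ids), size=counts[minority_label], replace=False)
    keep_mask = np.zeros(len(majority_ids), dtype=bool)
    keep_mask[keep] = True

    kept_majority = majority_ids[keep_mask]
    holdout_ids = majority_ids[~keep_mask]
    minority_ids = dataset.labels.index[dataset.labels == minority_label]

    train_ids = minority_ids.append(kept_majority)
    return dataset.subset(train_ids), dataset.subset(holdout_ids)


def weighted_sample(
    dataset: LabeledDataset, class_weights: dict[str, float] | str | None = None
) -> LabeledDataset:
    """Attach per-instance class weights; no instance is ever dropped.

    ``class_weights`` may be an explicit {label: weight} mapping, the string
    ``"paper"`` (minority 10, majority 7), or None for auto mode (inverse
    class frequency, normalized so the mean weight is 1).
    """
    counts = dataset.class_counts()
    if len(counts) < 2:
        raise ValueError("weighted sampling requires both classes to be present")
    minority_label = min(counts, key=lambda k: (counts[k], k))
    majority_label = next(k for k in counts if k != minority_label)

    if class_weights == "paper":
        mapping = {
            minority_label: PAPER_CLASS_WEIGHTS["minority"],
            majority_label: PAPER_CLASS_WEIGHTS["majority"],
        }
    elif class_weights is None:
        n = len(dataset)
        raw = {lab: n / (len(counts) * c) for lab, c in counts.items()}
        mean = sum(raw[lab] * counts[lab] for lab in raw) / n
        mapping = {lab: w / mean for lab, w in raw.items()}
    else:
        mapping = dict(class_weights)

    if any(w <= 0 for w in mapping.values()):
        raise ValueError("class weights must be positive")

    weights = dataset.labels.map(mapping).astype(float)
    return LabeledDataset(dataset.features, dataset.labels, weights)


def split_train_test(
    dataset: LabeledDataset, plan: SamplingPlan, out_dir: str | Path
) -> tuple[Path, Path]:
    """Materialize a sampling plan as a labeled feature-TSV pair."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    train_path = out_dir / "train.tsv"
    test_path = out_dir / "test.tsv"
    for ids, path in ((plan.train_ids, train_path), (plan.test_ids, test_path)):
        sub = dataset.subset(ids)
        table = sub.features.copy()
        table.insert(0, "label", sub.labels)
        if sub.weights is not None:
            table.insert(1, "weight", sub.weights)
        table.to_csv(path, sep="\t", index_label="id")
    return train_path, test_path
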