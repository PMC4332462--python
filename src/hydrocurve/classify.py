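"""Structural-class prediction by k-NN over the slope-difference distance.

Proteins are assigned to one of four coarse secondary-structure classes:
all-α, all-β, α/β (mainly parallel strands plus helices) and α+β
(antiparallel strands plus helices).  A query is classified by computing its
distance to every reference sequence, taking the k nearest, and letting the
class with the largest neighbor count win.  Evaluation is by jackknife
(leave-one-out): each sequence is predicted from all the others, reusing a
single precomputed distance matrix.

Tie handling is deterministic and documented: neighbors are ordered by
(distance, dataset index); a neighbor-count tie between classes goes to the
class whose tied neighbors have the smallest summed distance, and any
remaining tie falls to the fixed class order all-α < all-β < α/β < α+β.

Per-class quality is reported one-vs-rest: accuracy, sensitivity,
specificity, Matthews correlation coefficient, and ROC AUC where the score
for class c is the fraction of the k neighbors labeled c.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .distance import pairwise_matrix, profile_distance
from .encoding import AmbiguityPolicy, ProteinSequence, sequence_profile
from .indices import AminoAcidIndexTable

__all__ = [
    "CLASS_ORDER",
    "ClassifyError",
    "LabeledDataset",
    "ConfusionCounts",
    "ClassificationReport",
    "knn_predict",
    "jackknife_evaluate",
    "compute_metrics",
    "roc_auc",
]

#: Canonical class tokens, in fixed tie-breaking order.
CLASS_ORDER: tuple[str, ...] = (
    "all-alpha",
    "all-beta",
    "alpha/beta",
    "alpha+beta",
)

#: Default neighborhood size for structural-class prediction.
DEFAULT_K = 29


class ClassifyError(ValueError):
    """Raised for invalid datasets or classifier parameters."""


@dataclass(frozen=True)
class LabeledDataset:
    """Sequences plus an id → structural-class map (exactly one per id)."""

    sequences: tuple[ProteinSequence, ...]
    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequences", tuple(self.sequences))
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            raise ClassifyError("duplicate sequence ids")
        missing = [i for i in ids if i not in self.labels]
        if missing:
            raise ClassifyError(f"sequences without labels: {missing[:5]}")
        orphans = sorted(set(self.labels) - set(ids))
        if orphans:
            raise ClassifyError(f"labels without sequences: {orphans[:5]}")
        bad = sorted({c for c in self.labels.values() if c not in CLASS_ORDER})
        if bad:
            raise ClassifyError(
                f"unknown class tokens {bad}; expected one of {CLASS_ORDER}"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def classes(self) -> tuple[str, ...]:
        """Classes present in the data, in canonical order."""
        present = set(self.labels.values())
        return tuple(c for c in CLASS_ORDER if c in present)


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ClassifyError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _vote(
    neighbor_labels: Sequence[str], neighbor_dists: Sequence[float]
) -> str:
    """Majority vote with the documented two-stage tie break."""
    counts = {c: 0 for c in CLASS_ORDER}
    sums = {c: 0.0 for c in CLASS_ORDER}
    for lab, d in zip(neighbor_labels, neighbor_dists):
        counts[lab] += 1
        sums[lab] += d
    top = max(counts.values())
    tied = [c for c in CLASS_ORDER if counts[c] == top]
    if len(tied) == 1:
        return tied[0]
    best = min(sums[c] for c in tied)
    # residual ties fall to canonical class order (tied preserves it)
    return next(c for c in tied if sums[c] == best)


def knn_predict(
    query: ProteinSequence,
    train: LabeledDataset,
    k: int,
    table: AminoAcidIndexTable,
    policy: AmbiguityPolicy | str = AmbiguityPolicy.STRICT,
) -> str:
    """Predict the structural class of ``query`` from labeled references.

    The k nearest training sequences by slope-difference distance vote;
    ties resolve per the module's documented rule.  ``query`` need not be
    part of ``train``.
    """
    n = len(train)
    if n == 0:
        raise ClassifyError("empty training set")
    if not 1 <= k <= n:
        raise ClassifyError(f"k={k} out of range 1..{n}")
    qy = sequence_profile(query, table, policy)
    dists = [
        profile_distance(qy, sequence_profile(s, table, policy))
        for s in train.sequences
    ]
    order = sorted(range(n), key=lambda i: (dists[i], i))[:k]
    labels = [train.labels[train.sequences[i].id] for i in order]
    return _vote(labels, [dists[i] for i in order])


@dataclass(frozen=True)
class ClassificationReport:
    """Jackknife evaluation results.

    ``confusion`` is the 4x4 true-by-predicted matrix over the canonical
    class order; ``scores`` holds the per-sequence neighbor-fraction score
    for every class (the ROC input); ``per_class`` maps each class present
    in the data to accuracy/sensitivity/specificity/mcc/auc, with NaN where
    a metric's denominator vanishes.
    """

    predictions: Mapping[str, str]
    confusion: pd.DataFrame = field(repr=False)
    scores: pd.DataFrame = field(repr=False)
    per_class: Mapping[str, Mapping[str, float]]
    overall_accuracy: float

    def one_vs_rest(self, cls: str) -> ConfusionCounts:
        """Collapse the 4x4 confusion matrix to counts for one class."""
        return _one_vs_rest(self.confusion, cls)


def _one_vs_rest(confusion: pd.DataFrame, cls: str) -> ConfusionCounts:
    tp = int(confusion.loc[cls, cls])
    fn = int(confusion.loc[cls].sum() - tp)
    fp = int(confusion[cls].sum() - tp)
    tn = int(confusion.values.sum() - tp - fn - fp)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Evaluate accuracy, sensitivity, specificity and MCC from counts.

    accuracy    = (TP+TN) / (TP+TN+FP+FN)
    sensitivity = TP / (TP+FN)
    specificity = TN / (TN+FP)
    MCC         = (TP·TN − FP·FN) / sqrt((TN+FN)(TN+FP)(TP+FN)(TP+FP))

    A metric whose denominator is zero is reported as NaN with a warning,
    never silently coerced to 0.
    """
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn

    def _ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=3)
            return math.nan
        return num / den

    acc = _ratio(tp + tn, c.total, "accuracy")
    sens = _ratio(tp, tp + fn, "sensitivity")
    spec = _ratio(tn, tn + fp, "specificity")
    mcc_den_sq = (tn + fn) * (tn + fp) * (tp + fn) * (tp + fp)
    if mcc_den_sq == 0:
        warnings.warn("mcc undefined: zero marginal", stacklevel=2)
        mcc = math.nan
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(mcc_den_sq)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "mcc": mcc,
    }


def roc_auc(scores: Sequence[tuple[float, bool]]) -> float:
    """Area under the ROC curve with tied scores counted one-half.

    Equals the Mann–Whitney statistic: the probability that a random
    positive outscores a random negative.
    """
    if not scores:
        raise ClassifyError("empty score list")
    y_true = [bool(p) for _, p in scores]
    if all(y_true) or not any(y_true):
        raise ClassifyError("need at least one positive and one negative")
    y_score = [float(s) for s, _ in scores]
    return float(roc_auc_score(y_true, y_score))


def jackknife_evaluate(
    data: LabeledDataset,
    k: int,
    table: AminoAcidIndexTable,
    policy: AmbiguityPolicy | str = AmbiguityPolicy.STRICT,
) -> ClassificationReport:
    """Leave-one-out evaluation of the k-NN classifier.

    Each sequence is predicted with all the others as reference set.  The
    full pairwise distance matrix is computed once and reused for every
    held-out sequence.
    """
    n = len(data)
    if n < k + 1:
        raise ClassifyError(f"need at least k+1={k + 1} sequences, got {n}")
    if len(data.classes) < 2:
        raise ClassifyError("need at least 2 distinct classes")
    if k < 1:
        raise ClassifyError(f"k={k} must be positive")

    dm = pairwise_matrix(data.sequences, table, policy)
    ids = list(dm.labels)
    true = [data.labels[i] for i in ids]

    predictions: dict[str, str] = {}
    score_rows = np.zeros((n, len(CLASS_ORDER)))
    confusion = pd.DataFrame(
        0, index=list(CLASS_ORDER), columns=list(CLASS_ORDER), dtype=int
    )
    for i in range(n):
        others = [j for j in range(n) if j != i]
        order = sorted(others, key=lambda j: (dm.values[i, j], j))[:k]
        labels = [true[j] for j in order]
        dists = [dm.values[i, j] for j in order]
        pred = _vote(labels, dists)
        predictions[ids[i]] = pred
        confusion.loc[true[i], pred] += 1
        for ci, c in enumerate(CLASS_ORDER):
            score_rows[i, ci] = labels.count(c) / k

    scores = pd.DataFrame(score_rows, index=ids, columns=list(CLASS_ORDER))
    overall = float(np.trace(confusion.values)) / n

    per_class: dict[str, dict[str, float]] = {}
    for c in data.classes:
        metrics = compute_metrics(_one_vs_rest(confusion, c))
        metrics["auc"] = roc_auc(
            [(scores.loc[i, c], true_i == c) for i, true_i in zip(ids, true)]
        )
        per_class[c] = metrics

    return ClassificationReport(
        predictions=predictions,
        confusion=confusion,
        scores=scores,
        per_class=per_class,
        overall_accuracy=overall,
    )
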