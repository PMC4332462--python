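"""The slope-difference distance between sequences.

For two sequences with ordinate series ``y1`` (length ``l1``) and ``y2``
(length ``l2``), taking ``l1 >= l2`` (arguments are swapped if needed, which
makes the distance symmetric by construction):

    D = ( sum_{i<=l2} |y1_i - y2_i|  +  sum_{l2<i<=l1} |y1_i| ) / l1

For equal lengths this is the mean absolute ordinate difference; the tail
term charges the unmatched overhang of the longer sequence against the zero
baseline, so sequences of unequal length remain comparable without an
alignment.  The distance is non-negative, zero on identical sequences, and
symmetric; the triangle inequality is not claimed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .encoding import AmbiguityPolicy, ProteinSequence, sequence_profile
from .indices import AminoAcidIndexTable

__all__ = [
    "DistanceMatrixError",
    "DistanceMatrix",
    "MatrixCorrelation",
    "profile_distance",
    "distance",
    "pairwise_matrix",
    "matrix_correlation",
]


class DistanceMatrixError(ValueError):
    """Raised for invalid distance matrices or mismatched comparisons."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Labeled symmetric matrix of pairwise distances, zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise DistanceMatrixError(
                f"matrix shape {v.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise DistanceMatrixError("duplicate labels")
        if not np.allclose(v, v.T, atol=1e-12, rtol=0.0):
            raise DistanceMatrixError("matrix is not symmetric")
        if np.any(np.diag(v) != 0.0):
            raise DistanceMatrixError("diagonal must be zero")
        if np.any(v < 0.0):
            raise DistanceMatrixError("distances must be non-negative")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.labels), columns=list(self.labels)
        )

    def upper_triangle(self) -> np.ndarray:
        """Strict upper-triangle entries in row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]


def profile_distance(y1: np.ndarray, y2: np.ndarray) -> float:
    """Slope-difference distance between two ordinate series."""
    if len(y1) < len(y2):
        y1, y2 = y2, y1
    l1, l2 = len(y1), len(y2)
    if l2 == 0:
        raise ValueError("empty ordinate series")
    core = np.abs(y1[:l2] - y2).sum()
    tail = np.abs(y1[l2:]).sum()
    return float((core + tail) / l1)


def distance(
    s1: ProteinSequence,
    s2: ProteinSequence,
    table: AminoAcidIndexTable,
    policy: AmbiguityPolicy | str = AmbiguityPolicy.STRICT,
) -> float:
    """Slope-difference distance between two protein sequences."""
    return profile_distance(
        sequence_profile(s1, table, policy),
        sequence_profile(s2, table, policy),
    )


def pairwise_matrix(
    seqs: Sequence[ProteinSequence],
    table: AminoAcidIndexTable,
    policy: AmbiguityPolicy | str = AmbiguityPolicy.STRICT,
) -> DistanceMatrix:
    """All-against-all distance matrix; profiles are encoded once each."""
    if not seqs:
        raise DistanceMatrixError("need at least one sequence")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DistanceMatrixError(f"duplicate sequence ids: {dupes}")
    profiles = [sequence_profile(s, table, policy) for s in seqs]
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = profile_distance(profiles[i], profiles[j])
    return DistanceMatrix(labels=tuple(ids), values=m)


@dataclass(frozen=True)
class MatrixCorrelation:
    """Pearson correlation of two distance matrices, entry by entry.

    ``pairs`` holds the corresponding strict-upper-triangle values (columns
    ``label_i``, ``label_j``, ``d1``, ``d2``) for scatter plotting.
    """

    correlation: float
    pairs: pd.DataFrame

    def __float__(self) -> float:
        return self.correlation


def matrix_correlation(
    m1: DistanceMatrix, m2: DistanceMatrix
) -> MatrixCorrelation:
    """Correlate two distance matrices over their strict upper triangles.

    Both matrices must carry the same labels in the same order and be at
    least 3x3 so the triangle has three or more entries.
    """
    if m1.labels != m2.labels:
        raise DistanceMatrixError(
            f"label mismatch: {m1.labels} vs {m2.labels}"
        )
    n = len(m1.labels)
    if n < 3:
        raise DistanceMatrixError(
            "need at least 3 labels for a meaningful correlation"
        )
    t1 = m1.upper_triangle()
    t2 = m2.upper_triangle()
    if np.ptp(t1) == 0.0 or np.ptp(t2) == 0.0:
        raise DistanceMatrixError(
            "zero variance in a matrix triangle; correlation undefined"
        )
    r = float(stats.pearsonr(t1, t2).statistic)
    iu = np.triu_indices(n, k=1)
    pairs = pd.DataFrame(
        {
            "label_i": [m1.labels[i] for i in iu[0]],
            "label_j": [m1.labels[j] for j in iu[1]],
            "d1": t1,
            "d2": t2,
        }
    )
    return MatrixCorrelation(correlation=r, pairs=pairs)
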