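"""Sequence → 2D zigzag-curve encoding.

A protein sequence ``s1 s2 ... sn`` maps to the polyline through the origin
``P0 = (0, 0)`` and the points ``Pi = (i, y_i)`` where ``y_i`` is the
hydropathy/hydrophobicity ratio of the residue at position ``i``.  The
ordinate is a per-position value, not a cumulative sum: the slope between
consecutive points alternates with residue character, which is what makes
the curve a zigzag.  Only the ordinate series enters the distance metric;
the origin exists for plotting and coordinate export.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np

from .indices import AminoAcidIndexTable, STANDARD_RESIDUES

__all__ = [
    "AmbiguityPolicy",
    "SequenceError",
    "ProteinSequence",
    "Curve",
    "encode_sequence",
    "sequence_profile",
]

logger = logging.getLogger(__name__)


class AmbiguityPolicy(str, Enum):
    """How to treat residues absent from the index table (B, Z, X, U, O, J,
    gaps).  ``strict`` rejects them, ``skip`` drops them with a warning
    (renumbering positions), ``zero`` keeps them with ordinate 0."""

    STRICT = "strict"
    SKIP = "skip"
    ZERO = "zero"


class SequenceError(ValueError):
    """Raised for invalid protein sequences or unmappable residues."""


@dataclass(frozen=True)
class ProteinSequence:
    """An identifier plus an upper-case residue string.

    ``from_raw`` is the validating constructor: it case-folds, strips a
    terminal ``*`` stop character, and applies the ambiguity policy.
    """

    id: str
    residues: str

    @classmethod
    def from_raw(
        cls,
        id: str,
        residues: str,
        policy: AmbiguityPolicy | str = AmbiguityPolicy.STRICT,
    ) -> "ProteinSequence":
        policy = AmbiguityPolicy(policy)
        seq = residues.strip().upper()
        if seq.endswith("*"):
            logger.warning("%s: stripping terminal stop character '*'", id)
            seq = seq.rstrip("*")
        if policy is AmbiguityPolicy.STRICT:
            for pos, ch in enumerate(seq, start=1):
                if ch not in STANDARD_RESIDUES:
                    raise SequenceError(
                        f"{id}: non-standard residue {ch!r} at position {pos} "
                        "(policy 'strict'; use 'skip' or 'zero' to accept)"
                    )
        elif policy is AmbiguityPolicy.SKIP:
            kept = [ch for ch in seq if ch in STANDARD_RESIDUES]
            dropped = len(seq) - len(kept)
            if dropped:
                logger.warning(
                    "%s: dropped %d non-standard residue(s); positions renumbered",
                    id,
                    dropped,
                )
            seq = "".join(kept)
        if not seq:
            raise SequenceError(f"{id}: empty sequence")
        return cls(id=id, residues=seq)

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[str]:
        return iter(self.residues)


@dataclass(frozen=True)
class Curve:
    """The (x, y) point series of one encoded sequence, origin included.

    ``x`` runs 0..n (1-based residue positions after the origin), ``y`` holds
    the corresponding ordinates with ``y[0] = 0``.
    """

    id: str
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def points(self) -> list[tuple[int, float]]:
        return list(zip(self.x.tolist(), self.y.tolist()))

    @property
    def profile(self) -> np.ndarray:
        """Ordinates of residues 1..n (drops the origin point)."""
        return self.y[1:]


def _residue_ordinates(
    seq: ProteinSequence,
    table: AminoAcidIndexTable,
    policy: AmbiguityPolicy | str,
) -> np.ndarray:
    policy = AmbiguityPolicy(policy)
    ys = np.empty(len(seq), dtype=float)
    for i, ch in enumerate(seq.residues):
        if ch in table:
            ys[i] = table.y(ch)
        elif policy is AmbiguityPolicy.ZERO:
            ys[i] = 0.0
        else:
            raise SequenceError(
                f"{seq.id}: residue {ch!r} at position {i + 1} has no index "
                "table entry"
            )
    return ys


def encode_sequence(
    seq: ProteinSequence,
    table: AminoAcidIndexTable,
    policy: AmbiguityPolicy | str = AmbiguityPolicy.STRICT,
) -> Curve:
    """Encode a sequence of length n as its zigzag curve of n+1 points.

    Point 0 is the origin; point i is ``(i, y(residue_i))``.

    Raises
    ------
    SequenceError
        If the sequence is empty, or a residue has no table entry and the
        policy is strict.
    """
    if len(seq) == 0:
        raise SequenceError(f"{seq.id}: empty sequence")
    ys = _residue_ordinates(seq, table, policy)
    n = len(seq)
    return Curve(
        id=seq.id,
        x=np.arange(n + 1),
        y=np.concatenate(([0.0], ys)),
    )


def sequence_profile(
    seq: ProteinSequence,
    table: AminoAcidIndexTable,
    policy: AmbiguityPolicy | str = AmbiguityPolicy.STRICT,
) -> np.ndarray:
    """The length-n ordinate series of a sequence (curve minus origin)."""
    if len(seq) == 0:
        raise SequenceError(f"{seq.id}: empty sequence")
    return _residue_ordinates(seq, table, policy)
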