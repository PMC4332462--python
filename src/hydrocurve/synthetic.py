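"""Seeded synthetic sequence generators.

Random sequences are drawn i.i.d. over the 20-letter alphabet from a
composition profile; class-structured datasets give each class its own
profile so that classes differ in residue composition (and therefore in
mean curve ordinate).  The generators emulate composition structure only —
no positional correlation, domain architecture or evolutionary model — so
results on them demonstrate composition separability, not performance on
real protein families.

All randomness flows through one explicit integer seed; there is no hidden
global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .classify import LabeledDataset
from .encoding import ProteinSequence
from .indices import STANDARD_RESIDUES

__all__ = [
    "CompositionProfile",
    "random_sequences",
    "class_structured_dataset",
    "HYDROPHOBIC_PROFILE",
    "CHARGED_PROFILE",
]


@dataclass(frozen=True)
class CompositionProfile:
    """Sampling probabilities over the 20 standard residues."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = sorted(set(self.weights) - set(STANDARD_RESIDUES))
        if bad:
            raise ValueError(f"non-standard residues in profile: {bad}")
        w = np.array([self.weights.get(c, 0.0) for c in STANDARD_RESIDUES])
        if np.any(w < 0):
            raise ValueError("negative probability in profile")
        if abs(w.sum() - 1.0) >= 1e-9:
            raise ValueError(f"probabilities sum to {w.sum()}, not 1")
        object.__setattr__(self, "_probs", w)

    @property
    def probabilities(self) -> np.ndarray:
        """Probabilities aligned with the alphabetical residue order."""
        return self._probs  # type: ignore[attr-defined]

    @classmethod
    def uniform(cls) -> "CompositionProfile":
        return cls({c: 0.05 for c in STANDARD_RESIDUES})

    @classmethod
    def concentrated(cls, residues: str) -> "CompositionProfile":
        """Uniform over the given residues, zero elsewhere."""
        if not residues:
            raise ValueError("need at least one residue")
        p = 1.0 / len(residues)
        return cls({c: p for c in residues.upper()})


#: Composition concentrated on large hydrophobics (strongly positive ordinates).
HYDROPHOBIC_PROFILE = CompositionProfile.concentrated("ILVF")
#: Composition concentrated on charged residues (hydrophilic ordinates).
CHARGED_PROFILE = CompositionProfile.concentrated("DEKR")


def random_sequences(
    n: int,
    length: int,
    profile: CompositionProfile,
    seed: int,
    id_prefix: str = "seq",
) -> list[ProteinSequence]:
    """Draw ``n`` i.i.d. sequences of ``length`` residues from ``profile``."""
    if n < 1 or length < 1:
        raise ValueError("n and length must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(STANDARD_RESIDUES))
    seqs = []
    for i in range(n):
        residues = "".join(
            rng.choice(alphabet, size=length, p=profile.probabilities)
        )
        seqs.append(ProteinSequence(id=f"{id_prefix}_{i:04d}", residues=residues))
    return seqs


def class_structured_dataset(
    classes: Sequence[tuple[str, CompositionProfile, int]],
    length: int,
    seed: int,
) -> LabeledDataset:
    """Build a labeled dataset with one composition profile per class.

    ``classes`` is a list of (class label, profile, count).  Sequence ids
    embed the class label; the seed is split deterministically across
    classes via numpy's seed-sequence spawning.
    """
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    names = [c for c, _, _ in classes]
    if len(set(names)) != len(names):
        raise ValueError("duplicate class labels")
    if any(count < 1 for _, _, count in classes):
        raise ValueError("class counts must be >= 1")

    child_seeds = np.random.SeedSequence(seed).spawn(len(classes))
    sequences: list[ProteinSequence] = []
    labels: dict[str, str] = {}
    for (name, profile, count), ss in zip(classes, child_seeds):
        rng = np.random.default_rng(ss)
        alphabet = np.array(list(STANDARD_RESIDUES))
        safe = name.replace("/", "-")
        for i in range(count):
            sid = f"{safe}_{i:04d}"
            residues = "".join(
                rng.choice(alphabet, size=length, p=profile.probabilities)
            )
            sequences.append(ProteinSequence(id=sid, residues=residues))
            labels[sid] = name
    return LabeledDataset(sequences=tuple(sequences), labels=labels)
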