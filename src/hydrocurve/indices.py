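"""Amino-acid hydrophobicity/hydropathy index table.

Each of the 20 standard residues carries two raw physicochemical values: a
hydrophobicity index (EH) and a hydropathy index (Hp, the Kyte–Doolittle
style scale where positive means hydrophobic).  Both scales are mean-centered
over the 20 residues, and the per-residue ordinate used by the curve encoding
is the ratio of the centered values, ``y = hp1 / eh1``.

The built-in default table ships the raw values hard-coded; the centered
columns and ratios are always recomputed at load rather than transcribed.
For the default scales the EH values already sum to zero, so centering
leaves them unchanged, while the Hp mean is -0.49.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable

__all__ = [
    "STANDARD_RESIDUES",
    "IndexTableError",
    "AminoAcidIndexRecord",
    "AminoAcidIndexTable",
    "normalize_indices",
    "residue_y",
    "builtin_table",
    "load_index_table",
]

#: The 20 standard one-letter amino-acid codes, alphabetical.
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# Raw (code, EH, Hp) values for the 20 standard residues.  The centered
# columns are derived from these at load time, never stored.
_RAW_INDEX_VALUES: tuple[tuple[str, float, float], ...] = (
    ("A", 0.62, 1.8),
    ("C", 0.29, 2.5),
    ("D", -0.90, -3.5),
    ("E", -0.74, -3.5),
    ("F", 1.19, 2.8),
    ("G", 0.48, -0.4),
    ("H", -0.40, -3.2),
    ("I", 1.38, 4.5),
    ("K", -1.50, -3.9),
    ("L", 1.06, 3.8),
    ("M", 0.64, 1.9),
    ("N", -0.78, -3.5),
    ("P", 0.12, -1.6),
    ("Q", -0.85, -3.5),
    ("R", -2.53, -4.5),
    ("S", -0.18, -0.8),
    ("T", -0.05, -0.7),
    ("V", 1.08, 4.2),
    ("W", 0.81, -0.9),
    ("Y", 0.26, -1.3),
)


class IndexTableError(ValueError):
    """Raised when an amino-acid index table fails validation."""


@dataclass(frozen=True)
class AminoAcidIndexRecord:
    """One residue's raw, centered and ratio values (all dimensionless)."""

    code: str
    eh0: float
    hp0: float
    eh1: float
    hp1: float
    y: float


@dataclass(frozen=True)
class AminoAcidIndexTable:
    """Validated table of 20 residue records with centered indices.

    Construct through :func:`normalize_indices`, :func:`builtin_table` or
    :func:`load_index_table`; direct construction bypasses validation.
    """

    records: tuple[AminoAcidIndexRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_y_by_code", {r.code: r.y for r in self.records}
        )

    def record(self, code: str) -> AminoAcidIndexRecord:
        code = code.upper()
        for r in self.records:
            if r.code == code:
                return r
        raise IndexTableError(f"unknown residue code {code!r}")

    def y(self, code: str) -> float:
        """Ordinate ``hp1/eh1`` for ``code``; KeyError stays internal."""
        try:
            return self._y_by_code[code.upper()]  # type: ignore[attr-defined]
        except KeyError:
            raise IndexTableError(f"unknown residue code {code!r}") from None

    def __contains__(self, code: str) -> bool:
        return code.upper() in self._y_by_code  # type: ignore[attr-defined]

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(r.code for r in self.records)


def normalize_indices(
    raw: Iterable[tuple[str, float, float]]
) -> AminoAcidIndexTable:
    """Mean-center raw (code, eh0, hp0) triples and build the index table.

    The centered values are the raw values minus their mean over the 20
    standard residues; the per-residue ordinate is ``hp1 / eh1``.

    Raises
    ------
    IndexTableError
        If there are not exactly 20 triples, a code is duplicated or not a
        standard one-letter residue, or any centered hydrophobicity is zero
        (the ordinate would be undefined).
    """
    triples = [(str(c).upper(), float(e), float(h)) for c, e, h in raw]
    if len(triples) != 20:
        raise IndexTableError(
            f"expected 20 residue rows, got {len(triples)}"
        )
    codes = [c for c, _, _ in triples]
    if len(set(codes)) != 20:
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise IndexTableError(f"duplicate residue codes: {dupes}")
    bad = sorted(set(codes) - set(STANDARD_RESIDUES))
    if bad:
        raise IndexTableError(f"non-standard residue codes: {bad}")

    eh_mean = sum(e for _, e, _ in triples) / 20.0
    hp_mean = sum(h for _, _, h in triples) / 20.0

    records = []
    for code, eh0, hp0 in triples:
        eh1 = eh0 - eh_mean
        hp1 = hp0 - hp_mean
        if eh1 == 0.0:
            raise IndexTableError(
                f"centered hydrophobicity is zero for residue {code}; "
                "the ordinate hp1/eh1 is undefined"
            )
        records.append(
            AminoAcidIndexRecord(code, eh0, hp0, eh1, hp1, hp1 / eh1)
        )
    return AminoAcidIndexTable(tuple(records))


def residue_y(table: AminoAcidIndexTable, code: str) -> float:
    """Return the curve ordinate ``hp1/eh1`` for one residue code."""
    return table.y(code)


@lru_cache(maxsize=1)
def builtin_table() -> AminoAcidIndexTable:
    """The default EH/Hp index table (centered columns recomputed)."""
    return normalize_indices(_RAW_INDEX_VALUES)


def load_index_table(path: str | Path) -> AminoAcidIndexTable:
    """Load a raw index table from TSV with header ``code  eh0  hp0``.

    Alternate physicochemical scales can be supplied this way; the same
    validation and centering as the built-in table apply.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"code", "eh0", "hp0"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise IndexTableError(
                f"{path}: expected TSV header with columns code, eh0, hp0"
            )
        rows: list[tuple[str, float, float]] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                rows.append(
                    (row["code"], float(row["eh0"]), float(row["hp0"]))
                )
            except (TypeError, ValueError) as exc:
                raise IndexTableError(f"{path}:{lineno}: bad row: {exc}") from exc
    return normalize_indices(rows)
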