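"""Readers and writers for the package's file formats.

FASTA in (via Bio.SeqIO); curve coordinates, distance matrices (TSV or
relaxed PHYLIP square format) and classification reports out.  Writers
round-trip through the matching readers at the printed precision.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .classify import CLASS_ORDER, ClassificationReport
from .distance import DistanceMatrix, DistanceMatrixError
from .encoding import AmbiguityPolicy, Curve, ProteinSequence, SequenceError

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "write_matrix",
    "read_matrix",
    "write_curves",
    "write_report",
]

# Unicode and spelling aliases accepted in label files, canonicalized to
# the CLASS_ORDER tokens.
_CLASS_ALIASES = {
    "all-alpha": "all-alpha",
    "all-α": "all-alpha",
    "all-a": "all-alpha",
    "all-beta": "all-beta",
    "all-β": "all-beta",
    "all-b": "all-beta",
    "alpha/beta": "alpha/beta",
    "α/β": "alpha/beta",
    "a/b": "alpha/beta",
    "alpha+beta": "alpha+beta",
    "α+β": "alpha+beta",
    "a+b": "alpha+beta",
}


def read_fasta(
    path: str | Path,
    policy: AmbiguityPolicy | str = AmbiguityPolicy.STRICT,
) -> list[ProteinSequence]:
    """Read a FASTA file into validated sequences.

    The id is the header token up to the first whitespace; residues are
    upper-cased and the ambiguity policy is applied per record.  Duplicate
    ids and empty records are rejected with the record named.
    """
    path = Path(path)
    seqs: list[ProteinSequence] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise SequenceError(f"{path}: duplicate record id {record.id!r}")
        seen.add(record.id)
        raw = str(record.seq)
        if not raw.strip().strip("*"):
            raise SequenceError(f"{path}: record {record.id!r} is empty")
        seqs.append(ProteinSequence.from_raw(record.id, raw, policy))
    if not seqs:
        raise SequenceError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV ``id<TAB>class`` into a canonicalized map."""
    path = Path(path)
    labels: dict[str, str] = {}
    with path.open(newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if lineno == 1 and [c.lower() for c in row[:2]] == ["id", "class"]:
                continue  # optional header
            if len(row) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            sid, token = row[0].strip(), row[1].strip()
            cls = _CLASS_ALIASES.get(token.lower())
            if cls is None:
                raise ValueError(
                    f"{path}:{lineno}: unknown class token {token!r}; "
                    f"expected one of {sorted(set(_CLASS_ALIASES))}"
                )
            if sid in labels:
                raise ValueError(f"{path}:{lineno}: duplicate id {sid!r}")
            labels[sid] = cls
    if not labels:
        raise ValueError(f"{path}: no label rows found")
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("id\tclass\n")
        for sid, cls in labels.items():
            fh.write(f"{sid}\t{cls}\n")


def write_matrix(
    m: DistanceMatrix,
    path: str | Path,
    format: str = "tsv",
    precision: int = 4,
) -> None:
    """Write a distance matrix as labeled TSV or relaxed PHYLIP square.

    TSV has an id header row and id first column.  PHYLIP starts with the
    sequence count, then one row per sequence: name followed by distances.
    """
    path = Path(path)
    if precision < 1:
        raise ValueError("precision must be >= 1")
    fmt = f"{{:.{precision}f}}"
    if format == "tsv":
        with path.open("w") as fh:
            fh.write("\t" + "\t".join(m.labels) + "\n")
            for i, lab in enumerate(m.labels):
                row = "\t".join(fmt.format(v) for v in m.values[i])
                fh.write(f"{lab}\t{row}\n")
    elif format == "phylip":
        with path.open("w") as fh:
            fh.write(f"{len(m.labels)}\n")
            for i, lab in enumerate(m.labels):
                row = " ".join(fmt.format(v) for v in m.values[i])
                fh.write(f"{lab}  {row}\n")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_matrix(path: str | Path, format: str = "tsv") -> DistanceMatrix:
    """Read a distance matrix written by :func:`write_matrix`.

    A TSV holding only one triangle (empty cells elsewhere) is accepted and
    mirrored; the diagonal defaults to zero when blank.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise DistanceMatrixError(
                f"{path}: row and column labels differ"
            )
        v = df.to_numpy(dtype=float)
        # mirror a triangle-only file and default the diagonal to zero
        missing = np.isnan(v)
        v[missing] = v.T[missing]
        np.fill_diagonal(v, np.where(np.isnan(np.diag(v)), 0.0, np.diag(v)))
        if np.isnan(v).any():
            raise DistanceMatrixError(f"{path}: missing entries off-mirror")
        return DistanceMatrix(labels=tuple(df.index), values=v)
    if format == "phylip":
        with path.open() as fh:
            first = fh.readline().strip()
            n = int(first)
            labels, rows = [], []
            for line in fh:
                if not line.strip():
                    continue
                parts = line.split()
                labels.append(parts[0])
                rows.append([float(x) for x in parts[1:]])
        if len(labels) != n:
            raise DistanceMatrixError(f"{path}: expected {n} rows, got {len(labels)}")
        return DistanceMatrix(labels=tuple(labels), values=np.array(rows))
    raise ValueError(f"unknown matrix format {format!r}")


def write_curves(
    curves: Iterable[Curve], path: str | Path, sig_digits: int = 6
) -> None:
    """Write curve coordinates as long-format TSV ``id  position  y``."""
    with Path(path).open("w") as fh:
        fh.write("id\tposition\ty\n")
        for c in curves:
            for x, y in zip(c.x, c.y):
                fh.write(f"{c.id}\t{int(x)}\t{y:.{sig_digits}g}\n")


def write_report(
    report: ClassificationReport, path: str | Path, precision: int = 2
) -> None:
    """Write the per-class metrics table (percentages) plus overall accuracy."""
    cols = ["accuracy", "sensitivity", "specificity", "mcc", "auc"]
    with Path(path).open("w") as fh:
        fh.write("class\t" + "\t".join(cols) + "\n")
        for cls in CLASS_ORDER:
            if cls not in report.per_class:
                continue
            vals = report.per_class[cls]
            fh.write(
                cls
                + "\t"
                + "\t".join(f"{100 * vals[c]:.{precision}f}" for c in cols)
                + "\n"
            )
        fh.write(f"overall\t{100 * report.overall_accuracy:.{precision}f}\n")
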