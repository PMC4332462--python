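import pytest

from hydrocurve import ProteinSequence, builtin_table

# 30-residue yeast segments differing at exactly four positions
# (2: T/F, 11: K/N, 14: V/I, 27: L/F).
PROTEIN_I = "WTFESRNKPAKDPVILWLNGGPGCSSLTGL"
PROTEIN_II = "WFFESRNKPANDPIILWLNGGPGCSSFTGL"


@pytest.fixture(scope="session")
def table():
    return builtin_table()


@pytest.fixture
def protein_pair():
    return (
        ProteinSequence.from_raw("protein_I", PROTEIN_I),
        ProteinSequence.from_raw("protein_II", PROTEIN_II),
    )


def naive_ordinates(table, residues):
    """Independent per-residue ordinate lookup used by test oracles."""
    return [table.record(ch).hp1 / table.record(ch).eh1 for ch in residues]


def naive_distance(table, r1, r2):
    """Brute-force slope-difference distance written as an explicit loop."""
    if len(r1) < len(r2):
        r1, r2 = r2, r1
    y1 = naive_ordinates(table, r1)
    y2 = naive_ordinates(table, r2)
    total = 0.0
    for i in range(len(r2)):
        total += abs(y1[i] - y2[i])
    for i in range(len(r2), len(r1)):
        total += abs(y1[i])
    return total / len(r1)
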