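# Methods

## Encoding model

Each residue carries two dimensionless scale values: a hydrophobicity
index EH⁰ and a hydropathy index Hp⁰ (Kyte–Doolittle style; positive =
hydrophobic). Both columns are mean-centered over the 20 standard residues
at table load — the centered columns are always recomputed from the raw
values, never transcribed, so alternate scales supplied as a TSV
(`code/eh0/hp0`) get identical treatment. For the built-in scales the EH
column happens to sum to zero (centering is a no-op) and the Hp mean is
−0.49. Centering would be ill-defined as an ordinate source if any
centered hydrophobicity were exactly zero; that case is rejected at
validation rather than patched, since the built-in scale never triggers it.

A sequence of length n maps to n + 1 points: the origin plus
(i, Hp¹/EH¹ of residue i) for i = 1…n. The ordinate is deliberately a
per-position ratio and not a cumulative sum: the point-to-point slope then
alternates with residue character (a zigzag), and permuting a sequence
permutes its ordinate series identically. The origin point exists only for
plotting and coordinate export; it never enters the distance.

Full double precision is kept everywhere internally. Printed outputs
default to 4 decimals for distances and 2 decimals for percentage metrics,
with round-half-even at print time only.

## Distance

For ordinate series of lengths l₁ ≥ l₂ (arguments swapped if needed, which
makes the function symmetric by construction; an equal-length swap is a
no-op):

D = ( Σ_{i≤l₂} |y₁ᵢ − y₂ᵢ| + Σ_{l₂<i≤l₁} |y₁ᵢ| ) / l₁

Properties asserted by the test suite: identity, symmetry,
non-negativity, and the prefix-decomposition identity
l₁·D(S₁,S₂) = l₂·D(S₁[1..l₂], S₂) + Σ_{i>l₂}|y₁ᵢ|. The triangle
inequality is *not* claimed and not asserted. Matrix-to-matrix comparison
(e.g. against an externally computed alignment-based matrix) is Pearson
correlation over corresponding strict-upper-triangle entries; a
triangle-only reference file is mirrored on read.

## Classifier

k-NN over the distance above, four structural classes, default k = 29.
Determinism is engineered where the underlying procedure is silent:

- neighbors are ordered by (distance, dataset index), and exactly k taken;
- a neighbor-count tie between classes goes to the class whose tied
  neighbors have the smallest summed distance; any residual tie falls to
  the fixed order all-α < all-β < α/β < α+β;
- the ROC score of class c for a held-out sequence is the fraction of its
  k neighbors labeled c (one-vs-rest, per class).

Jackknife evaluation computes the pairwise matrix once and reuses it for
every held-out sequence. Metrics follow the standard confusion-count
formulas (accuracy, sensitivity, specificity, MCC); a metric whose
denominator vanishes is reported as NaN with a warning rather than
silently coerced to 0. AUC is the Mann–Whitney statistic with ties counted
one-half, computed via scikit-learn and cross-checked in the tests against
an explicit pair-count oracle.

The 639-domain low-identity benchmark used in the literature for this
family of classifiers is supported as a user-supplied FASTA + label file
but is not bundled (no stable source), and published accuracies on it are
not exactly reproducible in any case because the original tie-breaking and
score construction are unspecified; the choices above are this package's
own.

## Synthetic data

The generators draw sequences i.i.d. from a residue-composition profile;
a class-structured dataset gives each class its own profile. The default
benchmark uses two classes of 30 sequences of length 100 — a realistic
domain-scale length — one composition uniform on {I, L, V, F} (large
hydrophobics, ordinates ≈ 2.8–4.3) and one uniform on {D, E, K, R}
(charged residues, ordinates ≈ 1.6–4.1 but lower on average). Sequence
randomness flows through a single integer seed via numpy seed-sequence
spawning; there is no hidden global state.

What this emulates: classes that differ in residue composition, the signal
the distance actually measures. What it does not emulate: positional
correlation, conserved motifs, domain architecture, or evolutionary
relatedness. Passing the synthetic benchmark therefore demonstrates that
the pipeline separates composition-distinct classes, not that it attains
any particular accuracy on real structural-class datasets.

## Input handling

FASTA ids are the header token up to the first whitespace; residues are
upper-cased and a terminal `*` is stripped with a warning. Non-standard
residues (B, Z, X, U, O, J, gaps) have a configurable policy: `strict`
(reject, the default — errors carry record and position), `skip` (drop and
renumber, logged), or `zero` (keep with ordinate 0). Real-world FASTA
files are not clean; the default stays strict so silent distortion of the
ordinate series requires an explicit opt-in.

## Problem sizes in the test suite

The suite and the acceptance script run on: the 20-row index table, the
two printed 30-residue segments, 100 random toy classification datasets
(n ≤ 20), the 60-sequence synthetic benchmark at k = 3, and 1,000 random
pairs of lengths 1–200 for the metric properties. These sizes exercise
every code path, including both distance branches, while keeping a full
run in the low seconds.
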