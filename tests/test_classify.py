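import math
from collections import Counter

import numpy as np
import pytest

from hydrocurve import (
    CLASS_ORDER,
    CHARGED_PROFILE,
    HYDROPHOBIC_PROFILE,
    ClassifyError,
    ConfusionCounts,
    LabeledDataset,
    ProteinSequence,
    class_structured_dataset,
    compute_metrics,
    jackknife_evaluate,
    knn_predict,
    roc_auc,
)
from .conftest import naive_distance


def _random_dataset(rng, n, n_classes=3, max_len=25):
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    seqs, labels = [], {}
    for i in range(n):
        length = int(rng.integers(3, max_len))
        seqs.append(
            ProteinSequence.from_raw(
                f"s{i}", "".join(alphabet[j] for j in rng.integers(0, 20, length))
            )
        )
        labels[f"s{i}"] = CLASS_ORDER[int(rng.integers(0, n_classes))]
    # guarantee at least two classes
    labels["s0"], labels["s1"] = CLASS_ORDER[0], CLASS_ORDER[1]
    return LabeledDataset(sequences=tuple(seqs), labels=labels)


def _oracle_predict(table, query, data, k):
    """Exhaustive re-sort oracle using the brute-force distance."""
    scored = sorted(
        (naive_distance(table, query.residues, s.residues), i)
        for i, s in enumerate(data.sequences)
    )
    top = scored[:k]
    counts = Counter(data.labels[data.sequences[i].id] for _, i in top)
    best = max(counts.values())
    tied = [c for c in CLASS_ORDER if counts.get(c, 0) == best]
    if len(tied) > 1:
        sums = {
            c: sum(d for d, i in top if data.labels[data.sequences[i].id] == c)
            for c in tied
        }
        tied = [c for c in tied if sums[c] == min(sums.values())]
    return tied[0]


class TestKnnPredict:
    def test_homogeneous_labels(self, table):
        seqs = tuple(
            ProteinSequence.from_raw(f"s{i}", r)
            for i, r in enumerate(["ACD", "WYV", "KKK", "ILF"])
        )
        data = LabeledDataset(
            sequences=seqs, labels={s.id: "all-alpha" for s in seqs}
        )
        q = ProteinSequence.from_raw("q", "GGG")
        for k in (1, 2, 4):
            assert knn_predict(q, data, k, table) == "all-alpha"

    def test_exact_match_wins_at_k1(self, table):
        seqs = tuple(
            ProteinSequence.from_raw(f"s{i}", r)
            for i, r in enumerate(["ACDEF", "WWWWW", "KRKRK"])
        )
        labels = {"s0": "all-beta", "s1": "all-alpha", "s2": "alpha/beta"}
        data = LabeledDataset(sequences=seqs, labels=labels)
        q = ProteinSequence.from_raw("q", "WWWWW")
        assert knn_predict(q, data, 1, table) == "all-alpha"

    def test_majority_vote_two_vs_one(self, table):
        # neighborhood at k=3 holds two hydrophobic and one charged sequence
        seqs = tuple(
            ProteinSequence.from_raw(f"s{i}", r)
            for i, r in enumerate(["IIIII", "LLLLL", "DDDDD", "EEEEE", "KKKKK"])
        )
        labels = {
            "s0": "all-alpha",
            "s1": "all-alpha",
            "s2": "all-beta",
            "s3": "all-beta",
            "s4": "all-beta",
        }
        data = LabeledDataset(sequences=seqs, labels=labels)
        q = ProteinSequence.from_raw("q", "VVVVV")
        assert knn_predict(q, data, 3, table) == "all-alpha"

    def test_k_out_of_range(self, table):
        data = _random_dataset(np.random.default_rng(0), 5)
        q = ProteinSequence.from_raw("q", "ACD")
        with pytest.raises(ClassifyError, match="out of range"):
            knn_predict(q, data, 6, table)
        with pytest.raises(ClassifyError, match="out of range"):
            knn_predict(q, data, 0, table)

    def test_agrees_with_exhaustive_oracle(self, table):
        rng = np.random.default_rng(42)
        for trial in range(100):
            n = int(rng.integers(4, 20))
            data = _random_dataset(rng, n)
            k = int(rng.integers(1, n))
            q = ProteinSequence.from_raw(
                "q",
                "".join(
                    "ACDEFGHIKLMNPQRSTVWY"[j]
                    for j in rng.integers(0, 20, int(rng.integers(3, 25)))
                ),
            )
            assert knn_predict(q, data, k, table) == _oracle_predict(
                table, q, data, k
            )


class TestMetrics:
    def test_hand_computed_counts(self):
        m = compute_metrics(ConfusionCounts(tp=2, fn=1, tn=3, fp=0))
        assert m["sensitivity"] == pytest.approx(2 / 3, abs=1e-12)
        assert m["specificity"] == 1.0
        assert m["accuracy"] == pytest.approx(5 / 6, abs=1e-12)
        assert m["mcc"] == pytest.approx(6 / math.sqrt(72), abs=1e-12)

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionCounts(tp=4, tn=6, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_balanced_errors_give_zero_mcc(self):
        m = compute_metrics(ConfusionCounts(tp=1, tn=1, fp=1, fn=1))
        assert m["mcc"] == 0.0

    def test_zero_marginal_reported_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            m = compute_metrics(ConfusionCounts(tp=0, tn=3, fp=0, fn=0))
        assert math.isnan(m["sensitivity"])
        assert math.isnan(m["mcc"])
        assert not math.isnan(m["specificity"])


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([(0.9, True), (0.8, True), (0.2, False)]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([(0.5, True), (0.5, False), (0.5, True)]) == 0.5

    def test_three_of_four_pairs_ordered(self):
        scores = [(0.9, True), (0.4, True), (0.6, False), (0.1, False)]
        assert roc_auc(scores) == pytest.approx(0.75)

    def test_matches_mann_whitney_pair_count(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            n = int(rng.integers(4, 30))
            scores = [
                (float(rng.integers(0, 6)) / 5, bool(rng.integers(0, 2)))
                for _ in range(n)
            ]
            flags = [p for _, p in scores]
            if all(flags) or not any(flags):
                continue
            pos = [s for s, p in scores if p]
            neg = [s for s, p in scores if not p]
            pairs = sum(
                1.0 if a > b else 0.5 if a == b else 0.0
                for a in pos
                for b in neg
            )
            assert roc_auc(scores) == pytest.approx(
                pairs / (len(pos) * len(neg)), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        scores = [(0.9, True), (0.4, True), (0.6, False), (0.1, False)]
        warped = [(math.exp(3 * s), p) for s, p in scores]
        assert roc_auc(scores) == roc_auc(warped)

    def test_single_class_rejected(self):
        with pytest.raises(ClassifyError, match="positive"):
            roc_auc([(0.5, True), (0.7, True)])


@pytest.fixture(scope="module")
def two_class_data():
    return class_structured_dataset(
        [
            ("all-alpha", HYDROPHOBIC_PROFILE, 30),
            ("all-beta", CHARGED_PROFILE, 30),
        ],
        length=100,
        seed=2024,
    )


@pytest.fixture(scope="module")
def report(two_class_data, table):
    return jackknife_evaluate(two_class_data, k=3, table=table)


class TestJackknife:
    def test_separated_compositions_classified_accurately(self, report):
        assert report.overall_accuracy >= 0.9

    def test_confusion_sums_to_n(self, report, two_class_data):
        n = len(two_class_data)
        assert report.confusion.values.sum() == n
        for cls in CLASS_ORDER:
            row = int(report.confusion.loc[cls].sum())
            size = sum(1 for c in two_class_data.labels.values() if c == cls)
            assert row == size
        for cls in two_class_data.classes:
            assert report.one_vs_rest(cls).total == n

    def test_overall_accuracy_is_confusion_trace(self, report, two_class_data):
        trace = float(np.trace(report.confusion.values))
        assert report.overall_accuracy == trace / len(two_class_data)

    def test_deterministic(self, two_class_data, table):
        r1 = jackknife_evaluate(two_class_data, k=3, table=table)
        r2 = jackknife_evaluate(two_class_data, k=3, table=table)
        assert r1.predictions == r2.predictions
        assert r1.confusion.equals(r2.confusion)
        assert r1.per_class == r2.per_class

    def test_own_label_never_seen(self, table):
        """Altering a sequence's label cannot change its own prediction."""
        rng = np.random.default_rng(9)
        data = _random_dataset(rng, 12)
        target = data.sequences[3].id
        flipped = dict(data.labels)
        flipped[target] = (
            CLASS_ORDER[1] if data.labels[target] == CLASS_ORDER[0] else CLASS_ORDER[0]
        )
        other = LabeledDataset(sequences=data.sequences, labels=flipped)
        r1 = jackknife_evaluate(data, k=3, table=table)
        r2 = jackknife_evaluate(other, k=3, table=table)
        assert r1.predictions[target] == r2.predictions[target]

    def test_metric_bounds(self, report):
        for cls, m in report.per_class.items():
            for name in ("accuracy", "sensitivity", "specificity", "auc"):
                assert 0.0 <= m[name] <= 1.0
            assert -1.0 <= m["mcc"] <= 1.0

    def test_preconditions(self, table, two_class_data):
        with pytest.raises(ClassifyError, match="k"):
            jackknife_evaluate(two_class_data, k=60, table=table)
        seqs = two_class_data.sequences[:5]
        one_class = LabeledDataset(
            sequences=seqs, labels={s.id: "all-alpha" for s in seqs}
        )
        with pytest.raises(ClassifyError, match="classes"):
            jackknife_evaluate(one_class, k=2, table=table)
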