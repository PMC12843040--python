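"""Verification protocol: pair constraints, metric oracles, McNemar."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2 as chi2_dist

from petreid import (
    DatasetManifest,
    EmbeddingSet,
    PhotoRecord,
    build_pairs,
    eer,
    mcnemar,
    roc_auc,
    score_pairs,
    topk_accuracy,
)
from petreid.errors import ProtocolError, UndefinedMetricError, UsageError
from petreid.evaluation import VerificationPairSet, contingency


def _manifest(counts: dict[str, int]) -> DatasetManifest:
    return DatasetManifest(records=[
        PhotoRecord(photo_id=f"{ident}_p{j}", identity_id=ident, description="x")
        for ident, n in counts.items() for j in range(n)
    ])


def brute_force_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """All-pairs comparison: P(pos > neg) + 0.5 P(tie)."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestBuildPairs:
    def test_two_photo_identity_yields_single_pair(self):
        pairs = build_pairs(_manifest({"a": 2, "b": 2}), seed=0)
        from_a = [p for p in pairs.positives if p[0].startswith("a")]
        assert len(from_a) == 1

    def test_per_identity_cap_binds_with_generous_budget(self):
        # 30 photos admit C(30,2)=435 candidate pairs; the cap keeps 15
        pairs = build_pairs(_manifest({"big": 30, "other": 2}),
                            max_image_usage=1000, seed=0)
        from_big = [p for p in pairs.positives if p[0].startswith("big")]
        assert len(from_big) == 15

    def test_usage_cap_holds_exhaustively(self):
        pairs = build_pairs(_manifest({f"id{i}": 8 for i in range(10)}), seed=1)
        from collections import Counter

        usage = Counter()
        for a, b in pairs.positives + pairs.negatives:
            usage[a] += 1
            usage[b] += 1
        assert max(usage.values()) <= 5

    def test_negatives_matched_and_disjoint_labels(self):
        m = _manifest({f"id{i}": 4 for i in range(12)})
        pairs = build_pairs(m, seed=3)
        assert len(pairs.negatives) == len(pairs.positives)
        ident = {r.photo_id: r.identity_id for r in m.records}
        assert all(ident[a] != ident[b] for a, b in pairs.negatives)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_invariants_on_random_manifests(self, seed):
        rng = np.random.default_rng(seed)
        n_id = int(rng.integers(2, 20))
        counts = {f"id{i}": int(rng.integers(1, 12)) for i in range(n_id)}
        if not any(c >= 2 for c in counts.values()):
            counts["id0"] = 2
        m = _manifest(counts)
        pairs = build_pairs(m, seed=seed)
        pairs.validate(m)  # raises on any protocol violation

    def test_deterministic_per_seed(self):
        m = _manifest({f"id{i}": 5 for i in range(8)})
        p1, p2 = build_pairs(m, seed=9), build_pairs(m, seed=9)
        assert p1.positives == p2.positives and p1.negatives == p2.negatives

    def test_no_pairable_identity_is_protocol_error(self):
        with pytest.raises(ProtocolError):
            build_pairs(_manifest({"a": 1, "b": 1}))

    def test_single_identity_is_protocol_error(self):
        with pytest.raises(ProtocolError):
            build_pairs(_manifest({"a": 5}))


class TestScorePairs:
    def test_cosine_trivial_geometries(self):
        emb = EmbeddingSet(modality="vision", vectors={
            "a_p0": np.array([1.0, 0.0]), "a_p1": np.array([2.0, 0.0]),
            "b_p0": np.array([0.0, 1.0]), "b_p1": np.array([-1.0, 0.0]),
        })
        pairs = VerificationPairSet(
            positives=[("a_p0", "a_p1")],
            negatives=[("a_p0", "b_p0"), ("a_p0", "b_p1")],
        )
        scores, labels = score_pairs(emb, pairs)
        assert scores == pytest.approx([1.0, 0.0, -1.0])
        np.testing.assert_array_equal(labels, [1, 0, 0])

    def test_missing_embedding_names_photo(self):
        emb = EmbeddingSet(modality="vision", vectors={"a_p0": np.ones(2)})
        pairs = VerificationPairSet(positives=[("a_p0", "a_p1")])
        with pytest.raises(UsageError, match="a_p1"):
            score_pairs(emb, pairs)


class TestRocAuc:
    def test_dominance_and_ties(self):
        assert roc_auc([3, 4, 1, 2], [1, 1, 0, 0]) == 1.0
        assert roc_auc([1, 1, 1, 1], [1, 1, 0, 0]) == 0.5

    def test_worked_example(self):
        scores = [0.9, 0.4, 0.6, 0.1]
        labels = [1, 1, 0, 0]
        assert roc_auc(scores, labels) == pytest.approx(0.75)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_pos = int(rng.integers(1, 100))
        n_neg = int(rng.integers(1, 100))
        pos = np.round(rng.normal(size=n_pos), 2)  # rounding induces ties
        neg = np.round(rng.normal(size=n_neg), 2)
        scores = np.concatenate([pos, neg])
        labels = np.concatenate([np.ones(n_pos), np.zeros(n_neg)])
        assert roc_auc(scores, labels) == pytest.approx(
            brute_force_auc(pos, neg), abs=1e-12)

    def test_sign_reversal_maps_auc(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        assert roc_auc(-scores, labels) == pytest.approx(1 - roc_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [1, 1])


class TestEer:
    def test_perfect_separation(self):
        assert eer([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 0.0

    def test_exact_crossing_example(self):
        scores = [1, 1, 1, 0, 1, 0, 0, 0]
        labels = [1, 1, 1, 1, 0, 0, 0, 0]
        assert eer(scores, labels) == pytest.approx(0.25)

    def test_interleaved_example(self):
        assert eer([0.8, 0.2, 0.6, 0.4], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        labels[:2] = [0, 1]
        base = eer(scores, labels)
        for transform in (np.exp, lambda s: 3 * s + 1, np.tanh):
            assert eer(transform(scores), labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            eer([0.5], [0])


class TestTopK:
    def test_perfect_clusters(self, rng):
        vectors = {}
        for i in range(5):
            proto = rng.normal(size=6)
            for j in range(3):
                vectors[f"id{i}_p{j}"] = proto
        emb = EmbeddingSet(modality="vision", vectors=vectors)
        m = _manifest({f"id{i}": 3 for i in range(5)})
        acc, correct, queries = topk_accuracy(emb, m, ks=(1,))
        assert acc[1] == 1.0 and all(correct) and len(queries) == 15

    def test_adversarial_one_dimensional_layout(self):
        emb = EmbeddingSet(modality="vision", vectors={
            "A_p0": np.array([1.0, 0.0]), "A_p1": np.array([1.0, 0.6]),
            "B_p0": np.array([1.0, 0.5]), "B_p1": np.array([1.0, 1.0]),
        })
        m = _manifest({"A": 2, "B": 2})
        acc, _, _ = topk_accuracy(emb, m, ks=(1,))
        assert acc[1] == 0.0  # every nearest neighbour crosses identity

    def test_exhaustive_k_reaches_one(self, rng):
        m = _manifest({"a": 2, "b": 2})
        emb = EmbeddingSet(modality="vision",
                           vectors={r.photo_id: rng.normal(size=4) for r in m.records})
        acc, _, _ = topk_accuracy(emb, m, ks=(10,))
        assert acc[10] == 1.0

    def test_single_photo_identities_excluded_with_warning(self, rng):
        m = _manifest({"a": 2, "b": 1})
        emb = EmbeddingSet(modality="vision",
                           vectors={r.photo_id: rng.normal(size=4) for r in m.records})
        with pytest.warns(UserWarning, match="excluded"):
            _, _, queries = topk_accuracy(emb, m, ks=(1,))
        assert all(q.startswith("a") for q in queries)


class TestMcNemar:
    def test_symmetric_discordance(self):
        a = [True, False, True, False]
        b = [False, True, True, False]
        stat, p, direction = mcnemar(a, b)
        assert stat == 0.0 and p == 1.0 and direction == "tie"

    def test_one_sided_discordance_arithmetic(self):
        a = [True] * 10 + [True] * 5
        b = [False] * 10 + [True] * 5
        stat, p, direction = mcnemar(a, b)
        assert stat == 10.0
        assert p == pytest.approx(float(chi2_dist.sf(10.0, df=1)))
        assert direction == "A"

    def test_no_discordance_convention(self):
        stat, p, direction = mcnemar([True, False], [True, False])
        assert (stat, p, direction) == (0.0, 1.0, "tie")

    def test_contingency_counts_partition(self, rng):
        a = rng.integers(0, 2, size=50).astype(bool)
        b = rng.integers(0, 2, size=50).astype(bool)
        t = contingency(a, b)
        assert t.n == 50
        assert t.b == int(np.sum(a & ~b)) and t.c == int(np.sum(~a & b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(UsageError):
            mcnemar([True], [True, False])
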