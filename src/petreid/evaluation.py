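"""Constrained pair-based verification and retrieval evaluation.

Pair generation follows the controlled protocol: positive (same-animal)
pairs are sampled per identity with at most 15 pairs per identity and no
photo appearing more than 5 times across the union of all pairs; negative
(different-animal) pairs share the same usage budget — the counter carries
over from the positives — and are matched in count to the positives.

Verification scores are cosine similarities. Reported metrics:

* ROC AUC — probability that a random positive pair outscores a random
  negative pair (ties count 1/2);
* EER — the operating point where false positive rate equals false negative
  rate, linearly interpolated between adjacent ROC points when no exact
  crossing exists, ties broken toward the lower FPR;
* Top-k — leave-one-out retrieval over the pooled evaluation set: every
  photo queries the gallery of all other photos, and a query counts correct
  at k if any of its k nearest neighbours shares its identity;
* McNemar — paired comparison of two models' per-query Top-1 outcomes via
  chi^2 = (b - c)^2 / (b + c) on the discordant counts, without continuity
  correction; b + c = 0 gives (0, p = 1) by convention.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import chi2 as chi2_dist, rankdata
from sklearn.metrics import roc_curve

from .errors import (
    EmptyInputError,
    ProtocolError,
    UndefinedMetricError,
    UsageError,
)
from .records import DatasetManifest, EmbeddingSet

MAX_PAIRS_PER_IDENTITY = 15
MAX_IMAGE_USAGE = 5


@dataclass
class VerificationPairSet:
    """Same/different-identity photo pairs with shared usage bookkeeping."""

    positives: list[tuple[str, str]] = field(default_factory=list)
    negatives: list[tuple[str, str]] = field(default_factory=list)
    usage: Counter = field(default_factory=Counter)
    max_pairs_per_identity: int = MAX_PAIRS_PER_IDENTITY
    max_image_usage: int = MAX_IMAGE_USAGE

    def validate(self, manifest: DatasetManifest) -> None:
        identity_of = {r.photo_id: r.identity_id for r in manifest.records}
        seen: set[frozenset] = set()
        usage: Counter = Counter()
        per_identity: Counter = Counter()
        for a, b in self.positives:
            if a == b:
                raise ProtocolError(f"self-pair ({a}, {b})")
            if identity_of[a] != identity_of[b]:
                raise ProtocolError(f"positive pair ({a}, {b}) spans identities")
            per_identity[identity_of[a]] += 1
            key = frozenset((a, b))
            if key in seen:
                raise ProtocolError(f"duplicate pair ({a}, {b})")
            seen.add(key)
            usage[a] += 1
            usage[b] += 1
        for a, b in self.negatives:
            if identity_of[a] == identity_of[b]:
                raise ProtocolError(f"negative pair ({a}, {b}) shares an identity")
            key = frozenset((a, b))
            if key in seen:
                raise ProtocolError(f"duplicate pair ({a}, {b})")
            seen.add(key)
            usage[a] += 1
            usage[b] += 1
        if usage and max(usage.values()) > self.max_image_usage:
            worst = usage.most_common(1)[0]
            raise ProtocolError(f"photo {worst[0]} used {worst[1]} times (cap {self.max_image_usage})")
        if per_identity and max(per_identity.values()) > self.max_pairs_per_identity:
            worst = per_identity.most_common(1)[0]
            raise ProtocolError(
                f"identity {worst[0]} has {worst[1]} positive pairs (cap {self.max_pairs_per_identity})"
            )

    def digest(self) -> str:
        blob = json.dumps({"pos": sorted(self.positives), "neg": sorted(self.negatives)})
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def build_pairs(manifest: DatasetManifest,
                max_pairs_per_identity: int = MAX_PAIRS_PER_IDENTITY,
                max_image_usage: int = MAX_IMAGE_USAGE,
                seed: int = 0) -> VerificationPairSet:
    """Generate the constrained verification pair set, deterministic per seed."""
    groups = manifest.photos_by_identity()
    if len(groups) < 2:
        raise ProtocolError("pair generation needs at least 2 identities")
    if not any(len(p) >= 2 for p in groups.values()):
        raise ProtocolError("no identity has >= 2 photos; no positive pair exists")

    rng = np.random.default_rng([seed & 0x7FFFFFFF, 31])
    usage: Counter = Counter()
    positives: list[tuple[str, str]] = []
    identity_order = sorted(groups)
    rng.shuffle(identity_order)
    # Reserve half the per-image budget for the negative phase so the
    # negative pool (which shares the usage counter) can match the positive
    # count; the global cap still holds over the union of both pools.
    positive_budget = max(1, max_image_usage // 2)
    for identity in identity_order:
        photos = groups[identity]
        if len(photos) < 2:
            continue
        ii, jj = np.triu_indices(len(photos), k=1)
        order = rng.permutation(len(ii))
        taken = 0
        for k in order:
            if taken >= max_pairs_per_identity:
                break
            a, b = photos[ii[k]], photos[jj[k]]
            if usage[a] >= positive_budget or usage[b] >= positive_budget:
                continue
            positives.append((a, b))
            usage[a] += 1
            usage[b] += 1
            taken += 1

    # Negatives: same constraints, usage counter carried over from the
    # positives, count matched to the positives. Greedy on remaining budget:
    # always pair the two least-used photos of different identities.
    identity_of = {r.photo_id: r.identity_id for r in manifest.records}
    negatives: list[tuple[str, str]] = []
    seen: set[frozenset] = {frozenset(p) for p in positives}
    all_photos = [r.photo_id for r in manifest.records]
    rng.shuffle(all_photos)
    while len(negatives) < len(positives):
        available = [p for p in all_photos if usage[p] < max_image_usage]
        available.sort(key=lambda p: usage[p])
        placed = False
        for i, a in enumerate(available):
            for b in available[i + 1 :]:
                if identity_of[a] == identity_of[b]:
                    continue
                key = frozenset((a, b))
                if key in seen:
                    continue
                negatives.append((a, b))
                seen.add(key)
                usage[a] += 1
                usage[b] += 1
                placed = True
                break
            if placed:
                break
        if not placed:
            break
    if len(negatives) < len(positives):
        warnings.warn(
            f"usage caps admit only {len(negatives)} negative pairs for "
            f"{len(positives)} positives", stacklevel=2,
        )
    pairs = VerificationPairSet(
        positives=positives, negatives=negatives, usage=usage,
        max_pairs_per_identity=max_pairs_per_identity, max_image_usage=max_image_usage,
    )
    pairs.validate(manifest)
    assert all(identity_of[a] != identity_of[b] for a, b in negatives)
    return pairs


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def score_pairs(embeddings: EmbeddingSet,
                pairs: VerificationPairSet) -> tuple[np.ndarray, np.ndarray]:
    """Cosine similarity per pair; labels 1 for positives, 0 for negatives."""
    scores, labels = [], []
    for pool, label in ((pairs.positives, 1), (pairs.negatives, 0)):
        for a, b in pool:
            if a not in embeddings.vectors:
                raise UsageError(f"no embedding for photo_id {a!r}")
            if b not in embeddings.vectors:
                raise UsageError(f"no embedding for photo_id {b!r}")
            scores.append(cosine_similarity(embeddings[a], embeddings[b]))
            labels.append(label)
    return np.array(scores), np.array(labels)


def _check_two_classes(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise UndefinedMetricError("metric undefined with a single class present")


def roc_auc(scores, labels) -> float:
    """Rank-formulation ROC AUC: P(random positive outscores a random
    negative), ties counting 1/2 (exact, no curve integration)."""
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    _check_two_classes(labels)
    positive = labels == np.max(labels)
    ranks = rankdata(scores)  # midranks: ties contribute 1/2 automatically
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def eer(scores, labels) -> float:
    """Equal error rate with linear interpolation at the FPR/FNR crossing."""
    scores, labels = np.asarray(scores, dtype=float), np.asarray(labels)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    fnr = 1.0 - tpr
    diff = fnr - fpr  # starts at 1, ends at -1, non-increasing
    idx = int(np.argmax(diff <= 0))
    if diff[idx] == 0:
        return float(fpr[idx])
    f0, f1 = fpr[idx - 1], fpr[idx]
    g0, g1 = fnr[idx - 1], fnr[idx]
    s = (g0 - f0) / ((g0 - f0) + (f1 - g1))
    return float(f0 + s * (f1 - f0))


@dataclass
class ContingencyTable:
    """2x2 paired-outcome counts for the McNemar test."""

    a: int  # both correct
    b: int  # A correct, B incorrect
    c: int  # A incorrect, B correct
    d: int  # both incorrect

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency(correct_a, correct_b) -> ContingencyTable:
    ca = np.asarray(correct_a, dtype=bool)
    cb = np.asarray(correct_b, dtype=bool)
    if ca.shape != cb.shape:
        raise UsageError("outcome vectors must have equal length")
    return ContingencyTable(
        a=int(np.sum(ca & cb)),
        b=int(np.sum(ca & ~cb)),
        c=int(np.sum(~ca & cb)),
        d=int(np.sum(~ca & ~cb)),
    )


def mcnemar(correct_a, correct_b) -> tuple[float, float, str]:
    """McNemar chi^2 on discordant counts; returns (chi2, p, direction).

    ``direction`` names the model with fewer errors: 'A', 'B', or 'tie'.
    """
    table = contingency(correct_a, correct_b)
    b, c = table.b, table.c
    if b + c == 0:
        return 0.0, 1.0, "tie"
    stat = (b - c) ** 2 / (b + c)
    p = float(chi2_dist.sf(stat, df=1))
    direction = "A" if b > c else ("B" if c > b else "tie")
    return float(stat), p, direction


def topk_accuracy(embeddings: EmbeddingSet, manifest: DatasetManifest,
                  ks: tuple[int, ...] = (1, 5, 10),
                  ) -> tuple[dict[int, float], np.ndarray, list[str]]:
    """Leave-one-out retrieval accuracy.

    Returns (accuracy per k, per-query Top-1 correctness vector, query ids).
    Queries are photos whose identity has at least one other photo; the
    gallery for each query is every other photo in the manifest.
    """
    photo_ids = [r.photo_id for r in manifest.records]
    if not photo_ids:
        raise EmptyInputError("empty manifest")
    identity_of = {r.photo_id: r.identity_id for r in manifest.records}
    counts = Counter(identity_of.values())
    queries = [p for p in photo_ids if counts[identity_of[p]] >= 2]
    skipped = len(photo_ids) - len(queries)
    if skipped:
        warnings.warn(f"{skipped} single-photo-identity photos excluded as queries", stacklevel=2)
    if not queries:
        raise EmptyInputError("no identity has >= 2 photos; retrieval is undefined")

    mat = embeddings.matrix(photo_ids)
    norms = np.linalg.norm(mat, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    sims = (mat / norms) @ (mat / norms).T
    index_of = {p: i for i, p in enumerate(photo_ids)}
    labels = np.array([identity_of[p] for p in photo_ids])

    hits = {k: 0 for k in ks}
    top1_correct = np.zeros(len(queries), dtype=bool)
    for qi, q in enumerate(queries):
        i = index_of[q]
        order = np.argsort(-np.delete(sims[i], i))
        gallery_labels = np.delete(labels, i)[order]
        match = gallery_labels == identity_of[q]
        for k in ks:
            if match[: min(k, len(match))].any():
                hits[k] += 1
        top1_correct[qi] = bool(match[0]) if len(match) else False
    accuracy = {k: hits[k] / len(queries) for k in ks}
    return accuracy, top1_correct, queries


@dataclass
class EvalReport:
    """Full verification + retrieval report for one embedding set."""

    auc: float
    eer: float
    topk: dict[int, float]
    top1_correct: list[bool]
    query_ids: list[str]
    pair_digest: str
    n_pairs: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "auc": self.auc,
            "eer": self.eer,
            "topk": {str(k): v for k, v in self.topk.items()},
            "top1_correct": [bool(c) for c in self.top1_correct],
            "query_ids": self.query_ids,
            "pair_digest": self.pair_digest,
            "n_pairs": self.n_pairs,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        d = json.loads(Path(path).read_text())
        return cls(
            auc=d["auc"], eer=d["eer"],
            topk={int(k): v for k, v in d["topk"].items()},
            top1_correct=[bool(c) for c in d["top1_correct"]],
            query_ids=d["query_ids"], pair_digest=d["pair_digest"],
            n_pairs=d["n_pairs"],
        )


def evaluate(embeddings: EmbeddingSet, manifest: DatasetManifest,
             seed: int = 0, ks: tuple[int, ...] = (1, 5, 10),
             max_pairs_per_identity: int = MAX_PAIRS_PER_IDENTITY,
             max_image_usage: int = MAX_IMAGE_USAGE) -> EvalReport:
    """Run the full protocol: constrained pairs -> AUC/EER; retrieval -> Top-k."""
    pairs = build_pairs(manifest, max_pairs_per_identity, max_image_usage, seed)
    scores, labels = score_pairs(embeddings, pairs)
    accuracy, top1_correct, queries = topk_accuracy(embeddings, manifest, ks)
    return EvalReport(
        auc=roc_auc(scores, labels),
        eer=eer(scores, labels),
        topk=accuracy,
        top1_correct=list(top1_correct),
        query_ids=queries,
        pair_digest=pairs.digest(),
        n_pairs=len(pairs.positives) + len(pairs.negatives),
    )
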