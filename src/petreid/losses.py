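"""The combined metric-learning objective.

Two complementary terms shape the embedding space:

* **Triplet loss** — for anchor a, positive p (same identity), negative n
  (different identity), ``mean(max(0, ||f(a)-f(p)||^2 - ||f(a)-f(n)||^2 + alpha))``
  with margin ``alpha = 0.45``, on raw (unnormalized) embeddings, averaged
  over all mined triplets whether or not the hinge is active.

* **Intra-pair variance regularization** — with positive-pair cosine scores
  {s_pi} (mean s_p) and negative-pair scores {s_nj} (mean s_n)::

      L_var = mean_i max(0, (1-eps_pos)*s_p - s_pi)^2
            + mean_j max(0, s_nj - (1+eps_neg)*s_n)^2

  i.e. the square is applied to the hinged deficit, so only positives that
  fall below the tolerance-scaled positive mean and negatives that rise
  above the tolerance-scaled negative mean are penalized
  (eps_pos = eps_neg = 0.01).

* **Combined** — ``lambda1 * L_triplet + lambda2 * L_var`` with
  lambda1 = 1.0, lambda2 = 0.5: identity separation outranks intra-identity
  consistency.

All functions accept numpy arrays (returning floats) or autodiff Tensors
(returning Tensors, for training).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .errors import EmptyInputError, UsageError

_EPS = 1e-12


def _wrap(x) -> tuple[Tensor, bool]:
    if isinstance(x, Tensor):
        return x, True
    return Tensor(np.asarray(x, dtype=np.float64)), False


@dataclass
class TripletBatch:
    """Index triples into one batch's embedding rows."""

    anchors: np.ndarray
    positives: np.ndarray
    negatives: np.ndarray

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class SimilarityScores:
    """Within-batch cosine similarities of same/different-identity pairs."""

    positives: object  # (N_p,) array or Tensor
    negatives: object  # (N_n,) array or Tensor

    @property
    def mean_positive(self) -> float:
        data = self.positives.data if isinstance(self.positives, Tensor) else self.positives
        return float(np.mean(data))

    @property
    def mean_negative(self) -> float:
        data = self.negatives.data if isinstance(self.negatives, Tensor) else self.negatives
        return float(np.mean(data))


def triplet_loss(anchors, positives, negatives, margin: float = 0.45):
    """Mean hinged squared-distance triplet loss over (n, d) rows."""
    a, ta = _wrap(anchors)
    p, tp = _wrap(positives)
    n, tn = _wrap(negatives)
    if a.shape[0] == 0:
        raise EmptyInputError("no triplets provided")
    if not (a.shape == p.shape == n.shape):
        raise UsageError(f"triplet shape mismatch: {a.shape}, {p.shape}, {n.shape}")
    d_pos = ((a - p) ** 2).sum(axis=1)
    d_neg = ((a - n) ** 2).sum(axis=1)
    loss = (d_pos - d_neg + margin).relu().mean()
    return loss if (ta or tp or tn) else loss.item()


def intra_pair_variance_loss(scores: SimilarityScores, eps_pos: float = 0.01,
                             eps_neg: float = 0.01):
    """Hinge-then-square deviation of pair similarities from tolerance-scaled means."""
    sp, tp = _wrap(scores.positives)
    sn, tn = _wrap(scores.negatives)
    if sp.data.size == 0 or sn.data.size == 0:
        raise EmptyInputError("variance loss needs at least one positive and one negative pair")
    pos_term = (((1.0 - eps_pos) * sp.mean() - sp).relu() ** 2).mean()
    neg_term = ((sn - (1.0 + eps_neg) * sn.mean()).relu() ** 2).mean()
    loss = pos_term + neg_term
    return loss if (tp or tn) else loss.item()


def combined_loss(triplet, variance, lambda1: float = 1.0, lambda2: float = 0.5):
    """Weighted sum of the two loss components."""
    if isinstance(triplet, Tensor) or isinstance(variance, Tensor):
        return lambda1 * Tensor.as_tensor(triplet) + lambda2 * Tensor.as_tensor(variance)
    return lambda1 * float(triplet) + lambda2 * float(variance)


def cosine_similarity_matrix(embeddings):
    """Pairwise cosine similarities of the rows of (n, d) embeddings."""
    x, is_tensor = _wrap(embeddings)
    norms = ((x**2).sum(axis=1, keepdims=True) + _EPS).sqrt()
    xn = x / norms
    sim = xn @ xn.T
    return sim if is_tensor else sim.data


def _pair_indices(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Unordered (i < j) same-label and different-label index pairs."""
    n = len(labels)
    ii, jj = np.triu_indices(n, k=1)
    same = labels[ii] == labels[jj]
    return ii[same], jj[same], ii[~same], jj[~same]


def batch_to_pairs_and_triplets(embeddings, labels, mining: str = "batch_all",
                                ) -> tuple[TripletBatch, SimilarityScores]:
    """Mine triplets and collect pair similarity scores from one batch.

    ``batch_all`` enumerates every valid (anchor, positive, negative)
    combination; ``batch_hard`` keeps, per anchor, the most distant positive
    and the closest negative (squared Euclidean, computed on detached
    values so the mining choice itself is not differentiated through).
    """
    x, is_tensor = _wrap(embeddings)
    labels = np.asarray(labels)
    if x.shape[0] != len(labels):
        raise UsageError("embeddings and labels disagree in length")
    if len(np.unique(labels)) < 2:
        raise UsageError("batch needs >= 2 identities to form negative pairs")
    if mining not in ("batch_all", "batch_hard"):
        raise UsageError(f"unknown mining strategy {mining!r}")

    pi, pj, ni, nj = _pair_indices(labels)
    sim = cosine_similarity_matrix(x)
    if is_tensor:
        scores = SimilarityScores(positives=sim[pi, pj], negatives=sim[ni, nj])
    else:
        scores = SimilarityScores(positives=sim.data[pi, pj].copy(),
                                  negatives=sim.data[ni, nj].copy())

    same = labels[:, None] == labels[None, :]
    n = len(labels)
    if mining == "batch_all":
        anchors, positives, negatives = [], [], []
        for a in range(n):
            pos_idx = np.flatnonzero(same[a] & (np.arange(n) != a))
            neg_idx = np.flatnonzero(~same[a])
            for p in pos_idx:
                for ng in neg_idx:
                    anchors.append(a)
                    positives.append(p)
                    negatives.append(ng)
        triplets = TripletBatch(
            anchors=np.array(anchors, dtype=int),
            positives=np.array(positives, dtype=int),
            negatives=np.array(negatives, dtype=int),
        )
    else:  # batch_hard: one triplet per anchor that has a positive
        data = x.data
        d2 = ((data[:, None, :] - data[None, :, :]) ** 2).sum(axis=2)
        anchors, positives, negatives = [], [], []
        for a in range(n):
            pos_idx = np.flatnonzero(same[a] & (np.arange(n) != a))
            if pos_idx.size == 0:
                continue
            neg_idx = np.flatnonzero(~same[a])
            anchors.append(a)
            positives.append(pos_idx[np.argmax(d2[a, pos_idx])])
            negatives.append(neg_idx[np.argmin(d2[a, neg_idx])])
        triplets = TripletBatch(
            anchors=np.array(anchors, dtype=int),
            positives=np.array(positives, dtype=int),
            negatives=np.array(negatives, dtype=int),
        )
    return triplets, scores


def batch_loss(embeddings, labels, margin: float = 0.45, eps_pos: float = 0.01,
               eps_neg: float = 0.01, lambda1: float = 1.0, lambda2: float = 0.5,
               mining: str = "batch_all"):
    """Full combined objective of one batch; differentiable when given a Tensor."""
    x, is_tensor = _wrap(embeddings)
    triplets, scores = batch_to_pairs_and_triplets(
        x if is_tensor else x.data, labels, mining=mining
    )
    if len(triplets) == 0:
        raise EmptyInputError("no triplets could be mined from this batch")
    lt = triplet_loss(x[triplets.anchors], x[triplets.positives], x[triplets.negatives], margin)
    lv = intra_pair_variance_loss(scores, eps_pos, eps_neg)
    total = combined_loss(lt, lv, lambda1, lambda2)
    if is_tensor:
        return total
    return total.item() if isinstance(total, Tensor) else float(total)
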