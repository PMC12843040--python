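"""Balanced identity batch sampling.

Every batch holds exactly P distinct identities with exactly K distinct
photos each (P*K samples), so each identity exerts equal gradient pressure
regardless of how many photos it owns. The defaults P = 58, K = 2 give the
116-sample batches used throughout the study.

Epoch semantics: one epoch visits ``floor(n_eligible / P)`` batches with no
identity appearing twice in the same epoch; the leftover identities rotate
across epochs because the identity permutation is drawn per (seed, epoch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SamplingError
from .records import DatasetManifest


@dataclass
class BatchPlan:
    """Ordered batches of (identity_id, photo_id) pairs."""

    batches: list[list[tuple[str, str]]]
    P: int
    K: int

    def validate(self) -> None:
        for i, batch in enumerate(self.batches):
            if len(batch) != self.P * self.K:
                raise SamplingError(f"batch {i} has {len(batch)} samples, expected {self.P * self.K}")
            by_id: dict[str, set[str]] = {}
            for identity, photo in batch:
                by_id.setdefault(identity, set()).add(photo)
            if len(by_id) != self.P:
                raise SamplingError(f"batch {i} has {len(by_id)} identities, expected {self.P}")
            for identity, photos in by_id.items():
                if len(photos) != self.K:
                    raise SamplingError(
                        f"batch {i}: identity {identity} contributes {len(photos)} photos, expected {self.K}"
                    )
            all_photos = [photo for _, photo in batch]
            if len(set(all_photos)) != len(all_photos):
                raise SamplingError(f"batch {i} repeats a photo")

    def __len__(self) -> int:
        return len(self.batches)


def eligible_identities(manifest: DatasetManifest, K: int) -> tuple[list[str], list[str]]:
    """Split identities into (eligible, excluded) by the >= K photos rule."""
    groups = manifest.photos_by_identity()
    eligible = [i for i, photos in groups.items() if len(photos) >= K]
    excluded = [i for i, photos in groups.items() if len(photos) < K]
    return eligible, excluded


def plan_epoch(manifest: DatasetManifest, P: int = 58, K: int = 2,
               seed: int = 0, epoch: int = 0) -> BatchPlan:
    """Plan one epoch of balanced P x K batches, deterministic given (seed, epoch).

    Identity selection is uniform over eligible identities regardless of
    photo count; photos within an identity are drawn uniformly without
    replacement per batch.
    """
    groups = manifest.photos_by_identity()
    eligible, excluded = eligible_identities(manifest, K)
    if excluded:
        warnings.warn(
            f"{len(excluded)} identities with fewer than K={K} photos excluded from sampling",
            stacklevel=2,
        )
    if len(eligible) < P:
        raise SamplingError(
            f"need at least P={P} identities with >= {K} photos, "
            f"have {len(eligible)} (short by {P - len(eligible)})"
        )
    rng = np.random.default_rng([seed & 0x7FFFFFFF, epoch])
    order = [eligible[i] for i in rng.permutation(len(eligible))]
    n_batches = len(eligible) // P
    batches: list[list[tuple[str, str]]] = []
    for b in range(n_batches):
        batch: list[tuple[str, str]] = []
        for identity in order[b * P : (b + 1) * P]:
            photos = groups[identity]
            chosen = rng.choice(len(photos), size=K, replace=False)
            batch.extend((identity, photos[j]) for j in chosen)
        batches.append(batch)
    plan = BatchPlan(batches=batches, P=P, K=K)
    plan.validate()
    return plan
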