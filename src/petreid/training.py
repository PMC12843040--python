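"""The fine-tuning loop.

One configuration drives every run — balanced P x K batches, Adam at a fixed
learning rate (betas (0.9, 0.999), eps 1e-8, no weight decay, no schedule,
no early stopping), a fixed number of epochs, and partial freezing of the
encoder blocks — so unimodal and multimodal models are compared under
identical optimization conditions. When a fusion head is configured the
loss is computed on the fused embeddings; otherwise on the vision
embeddings. Runs are fully reproducible given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .autodiff import Adam
from .config import RunConfig
from .encoders import EncoderAdapter, FreezePolicy, partition_trainable
from .errors import ConfigError, UsageError
from .fusion import FusionModel
from .losses import batch_loss
from .records import DatasetManifest, EmbeddingSet
from .sampling import plan_epoch


@dataclass
class TrainState:
    """Bookkeeping of one training run."""

    loss_trace: list[float] = field(default_factory=list)
    epoch_mean_losses: list[float] = field(default_factory=list)
    epochs_completed: int = 0
    config_digest: str = ""
    seed: int = 0

    @property
    def steps(self) -> int:
        return len(self.loss_trace)


def inputs_from_embeddings(embeddings: EmbeddingSet) -> dict[str, np.ndarray]:
    """Per-photo raw inputs for an EmbeddingAdapter."""
    return dict(embeddings.vectors)


def text_inputs_from_manifest(manifest: DatasetManifest) -> dict[str, str]:
    """Per-photo description strings for a text encoder."""
    out = {}
    for rec in manifest.records:
        if rec.description is None:
            raise UsageError(f"record {rec.photo_id} has no description for the text branch")
        out[rec.photo_id] = rec.description
    return out


def train(
    manifest: DatasetManifest,
    vision_encoder: EncoderAdapter,
    config: RunConfig,
    vision_inputs: Mapping[str, object],
    text_encoder: EncoderAdapter | None = None,
    text_inputs: Mapping[str, object] | None = None,
    fusion: FusionModel | None = None,
) -> TrainState:
    """Run the fine-tuning loop in place and return the training state.

    ``vision_inputs`` / ``text_inputs`` map photo_id to the raw input each
    encoder consumes (an image array, a description string, or a stored
    embedding vector).
    """
    multimodal = fusion is not None
    if multimodal and (text_encoder is None or text_inputs is None):
        raise ConfigError("fusion requires a text encoder and text inputs")
    if config.fusion_kind == "none" and multimodal:
        raise ConfigError("fusion model supplied but fusion_kind is 'none'")

    policy = FreezePolicy(config.unfrozen_blocks)
    partition_trainable(vision_encoder, policy)
    params = list(vision_encoder.parameters())
    if multimodal:
        partition_trainable(text_encoder, policy)
        params += list(text_encoder.parameters())
        params += list(fusion.parameters())

    optimizer = Adam(params, lr=config.learning_rate)
    state = TrainState(config_digest=config.digest(), seed=config.seed)

    for epoch in range(config.epochs):
        plan = plan_epoch(
            manifest, P=config.batch_identities, K=config.photos_per_identity,
            seed=config.seed, epoch=epoch,
        )
        epoch_losses = []
        for batch_idx, batch in enumerate(plan.batches):
            labels = np.array([identity for identity, _ in batch])
            photo_ids = [photo for _, photo in batch]
            v = vision_encoder.forward([vision_inputs[p] for p in photo_ids])
            if multimodal:
                t = text_encoder.forward([text_inputs[p] for p in photo_ids])
                embeddings = fusion.fuse(v, t)
            else:
                embeddings = v
            loss = batch_loss(
                embeddings, labels,
                margin=config.loss.margin,
                eps_pos=config.loss.eps_pos, eps_neg=config.loss.eps_neg,
                lambda1=config.loss.lambda1, lambda2=config.loss.lambda2,
                mining=config.loss.mining,
            )
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {batch_idx} "
                    f"(step {state.steps})"
                )
            optimizer.zero_grad()
            loss.backward()
            if config.learning_rate > 0:
                optimizer.step()
            state.loss_trace.append(loss.item())
            epoch_losses.append(loss.item())
        state.epoch_mean_losses.append(float(np.mean(epoch_losses)) if epoch_losses else np.nan)
        state.epochs_completed = epoch + 1
    return state


def encode_all(
    encoder: EncoderAdapter,
    manifest: DatasetManifest,
    inputs: Mapping[str, object],
    modality: str | None = None,
    batch_size: int = 128,
) -> EmbeddingSet:
    """Inference pass over a whole manifest, batched, into an EmbeddingSet."""
    photo_ids = [r.photo_id for r in manifest.records]
    vectors: dict[str, np.ndarray] = {}
    for start in range(0, len(photo_ids), batch_size):
        chunk = photo_ids[start : start + batch_size]
        mat = encoder.encode([inputs[p] for p in chunk])
        for i, pid in enumerate(chunk):
            vectors[pid] = mat[i]
    return EmbeddingSet(modality=modality or encoder.modality, vectors=vectors)


def fuse_all(
    fusion: FusionModel,
    vision: EmbeddingSet,
    text: EmbeddingSet,
) -> EmbeddingSet:
    """Inference-mode fusion of two stored embedding sets (shared keys)."""
    ids = [p for p in vision.vectors if p in text.vectors]
    if not ids:
        raise UsageError("no shared photo_ids between the two embedding sets")
    fused = fusion.fuse(vision.matrix(ids), text.matrix(ids))
    return EmbeddingSet(modality="fused", vectors={p: fused[i] for i, p in enumerate(ids)})
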