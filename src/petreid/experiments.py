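"""Desk-scale experiment drivers.

These wrap the full pipeline — synthetic corpus, adapters, fusion, the
fixed training recipe, and the verification protocol — into reproducible
studies small enough for a CPU. The fusion study trains the embedding
adapters from scratch, so it uses a learning rate of 1e-3 (the fine-tuning
rate of 1e-4 is calibrated for pretrained backbones and underfits a
from-scratch trunk within the fixed 10-epoch budget).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .encoders import EmbeddingAdapter
from .evaluation import topk_accuracy
from .fusion import FusionModel
from .records import DatasetManifest, EmbeddingSet
from .synthetic import SynthConfig, generate_dataset
from .training import encode_all, fuse_all, inputs_from_embeddings, train

STUDY_P = 8
STUDY_K = 2
STUDY_IDENTITIES = 50
STUDY_LR = 1e-3
STUDY_DIM = 64


def train_and_score(manifest: DatasetManifest, vision: EmbeddingSet,
                    text: EmbeddingSet, fusion_kind: str, seed: int,
                    learning_rate: float = STUDY_LR,
                    ) -> tuple[float, FusionModel | None]:
    """Train one configuration and return its leave-one-out Top-1 accuracy."""
    config = RunConfig(
        seed=seed, batch_identities=STUDY_P, photos_per_identity=STUDY_K,
        learning_rate=learning_rate, epochs=10, fusion_kind=fusion_kind,
    )
    vision_encoder = EmbeddingAdapter("vision", vision.dim, d_model=STUDY_DIM,
                                      embedding_dim=STUDY_DIM, seed=seed)
    vision_inputs = inputs_from_embeddings(vision)
    if fusion_kind == "none":
        train(manifest, vision_encoder, config, vision_inputs)
        embeddings = encode_all(vision_encoder, manifest, vision_inputs)
        return topk_accuracy(embeddings, manifest, ks=(1,))[0][1], None
    text_encoder = EmbeddingAdapter("text", text.dim, d_model=STUDY_DIM,
                                    embedding_dim=STUDY_DIM, seed=seed)
    text_inputs = inputs_from_embeddings(text)
    fusion = FusionModel(fusion_kind, STUDY_DIM, STUDY_DIM, shared_dim=STUDY_DIM,
                         seed=seed)
    train(manifest, vision_encoder, config, vision_inputs,
          text_encoder=text_encoder, text_inputs=text_inputs, fusion=fusion)
    fused = fuse_all(
        fusion,
        encode_all(vision_encoder, manifest, vision_inputs),
        encode_all(text_encoder, manifest, text_inputs),
    )
    return topk_accuracy(fused, manifest, ks=(1,))[0][1], fusion


@dataclass
class FusionStudyResult:
    """Per-seed Top-1 accuracies of the three configurations."""

    vision_only: list[float] = field(default_factory=list)
    concat: list[float] = field(default_factory=list)
    gated: list[float] = field(default_factory=list)

    def means(self) -> dict[str, float]:
        return {
            "vision_only": float(np.mean(self.vision_only)),
            "concat": float(np.mean(self.concat)),
            "gated": float(np.mean(self.gated)),
        }

    @staticmethod
    def paired_not_worse(a: list[float], b: list[float], z: float = 1.645) -> bool:
        """One-sided paired check: mean(a - b) not significantly below zero."""
        d = np.asarray(a) - np.asarray(b)
        se = d.std(ddof=1) / np.sqrt(len(d)) if len(d) > 1 else 0.0
        return bool(d.mean() + z * se >= 0)


def fusion_study(seeds: list[int], n_identities: int = STUDY_IDENTITIES,
                 ) -> FusionStudyResult:
    """Train vision-only, concat and gated fusion on complementary modalities."""
    result = FusionStudyResult()
    for seed in seeds:
        cfg = SynthConfig(n_identities=n_identities, seed=seed)
        manifest, vision, text = generate_dataset(cfg)
        result.vision_only.append(
            train_and_score(manifest, vision, text, "none", seed)[0])
        result.concat.append(
            train_and_score(manifest, vision, text, "concat", seed)[0])
        result.gated.append(
            train_and_score(manifest, vision, text, "gated", seed)[0])
    return result


def gate_recovery_study(seeds: list[int], n_identities: int = STUDY_IDENTITIES,
                        ) -> tuple[float, float]:
    """Mean learned gate weights (image, text) when text is pure noise."""
    image_w, text_w = [], []
    for seed in seeds:
        cfg = SynthConfig(n_identities=n_identities, seed=seed,
                          text_informativeness=0.0)
        manifest, vision, text = generate_dataset(cfg)
        _, fusion = train_and_score(manifest, vision, text, "gated", seed)
        g = fusion.last_gates.mean(axis=0)
        image_w.append(g[0])
        text_w.append(g[1])
    return float(np.mean(image_w)), float(np.mean(text_w))
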