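"""Encoder adapters, the partial-freeze transfer policy, and tiny reference encoders.

An encoder adapter maps raw modality inputs (images, descriptions, or
precomputed embedding vectors) to fixed-dimension embedding vectors. All
adapters expose the same contract:

* ``blocks()`` — the ordered list of transformer/residual blocks, the unit
  the freeze policy reasons about;
* ``input_parameters()`` / ``head_parameters()`` — non-block parameters:
  patch/token embedding layers stay frozen under partial freezing, while the
  final projection head (which sits after the last block) stays trainable;
* ``forward(inputs)`` — differentiable batch encoding returning a Tensor;
* ``encode(inputs)`` — inference-mode numpy encoding (deterministic).

The tiny reference encoders (a 2-block patch transformer for images, a
token-embedding + 1-block transformer for text) are small enough for CPU
test runs while exercising the same block semantics as large pretrained
backbones.
"""

from __future__ import annotations

import re
import zlib
from dataclasses import dataclass

import numpy as np

from .autodiff import Parameter, Tensor
from .errors import ConfigError, UsageError
from .nn import Module, ResidualMLPBlock, TransformerBlock, glorot, linear, stack_rows
from .records import EmbeddingSet

DEFAULT_UNFROZEN_BLOCKS = 5


@dataclass(frozen=True)
class FreezePolicy:
    """Unfreeze only the final N blocks; everything earlier stays frozen."""

    n_unfrozen_final_blocks: int = DEFAULT_UNFROZEN_BLOCKS

    def __post_init__(self) -> None:
        if self.n_unfrozen_final_blocks < 0:
            raise ConfigError("n_unfrozen_final_blocks must be non-negative")


def partition_trainable(encoder: "EncoderAdapter", policy: FreezePolicy) -> dict[str, int]:
    """Apply the freeze policy in place and report block counts.

    Exactly ``min(depth, n_unfrozen)`` final blocks become trainable; earlier
    blocks and the input/embedding layer are frozen; the projection head
    (after the last block) remains trainable.
    """
    blocks = encoder.blocks()
    n_train = min(len(blocks), policy.n_unfrozen_final_blocks)
    cut = len(blocks) - n_train
    for i, block in enumerate(blocks):
        for p in block.parameters():
            p.trainable = i >= cut
    for p in encoder.input_parameters():
        p.trainable = False
    for p in encoder.head_parameters():
        p.trainable = True
    return {"trainable_blocks": n_train, "frozen_blocks": cut}


class EncoderAdapter(Module):
    """Common contract for vision/text/embedding encoders."""

    modality: str
    embedding_dim: int

    def blocks(self) -> list[Module]:
        raise NotImplementedError

    def input_parameters(self) -> list[Parameter]:
        raise NotImplementedError

    def head_parameters(self) -> list[Parameter]:
        raise NotImplementedError

    @property
    def depth(self) -> int:
        return len(self.blocks())

    def forward(self, inputs) -> Tensor:
        raise NotImplementedError

    def encode(self, inputs) -> np.ndarray:
        """Inference-mode encoding: one row per input."""
        return self.forward(inputs).data.copy()

    def parameters(self) -> list[Parameter]:
        out = list(self.input_parameters())
        for b in self.blocks():
            out.extend(b.parameters())
        out.extend(self.head_parameters())
        return out


class TinyVisionEncoder(EncoderAdapter):
    """2-block patch transformer over small raster images.

    Images are split into non-overlapping square patches, linearly embedded,
    passed through two transformer blocks, mean-pooled and projected.
    """

    modality = "vision"

    def __init__(self, image_size: int = 64, patch_size: int = 8, d_model: int = 32,
                 embedding_dim: int = 32, n_blocks: int = 2, seed: int = 0):
        super().__init__()
        if image_size % patch_size:
            raise ConfigError("patch_size must divide image_size")
        self.image_size = image_size
        self.patch_size = patch_size
        self.d_model = d_model
        self.embedding_dim = embedding_dim
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 101])
        patch_dim = patch_size * patch_size * 3
        self.patch_embed = self._param(glorot(rng, patch_dim, d_model), "vision.patch_embed")
        n_patches = (image_size // patch_size) ** 2
        self.pos_embed = self._param(
            0.02 * rng.standard_normal((n_patches, d_model)), "vision.pos_embed"
        )
        self._blocks = [TransformerBlock(d_model, rng, f"vision.block{i}") for i in range(n_blocks)]
        self.head = self._param(glorot(rng, d_model, embedding_dim), "vision.head")

    def blocks(self) -> list[Module]:
        return list(self._blocks)

    def input_parameters(self) -> list[Parameter]:
        return [self.patch_embed, self.pos_embed]

    def head_parameters(self) -> list[Parameter]:
        return [self.head]

    def _patchify(self, image: np.ndarray) -> np.ndarray:
        s, p = self.image_size, self.patch_size
        if image.shape != (s, s, 3):
            raise UsageError(f"expected image of shape {(s, s, 3)}, got {image.shape}")
        patches = image.reshape(s // p, p, s // p, p, 3).transpose(0, 2, 1, 3, 4)
        return patches.reshape(-1, p * p * 3) / 255.0

    def forward(self, images) -> Tensor:
        if isinstance(images, np.ndarray) and images.ndim == 3:
            images = [images]
        rows = []
        for image in images:
            if isinstance(image, str):
                raise UsageError("vision encoder received text input (mixed-modality batch?)")
            x = Tensor(self._patchify(np.asarray(image))) @ self.patch_embed + self.pos_embed
            for block in self._blocks:
                x = block.forward(x)
            rows.append(linear(x.mean(axis=0, keepdims=True), self.head).reshape(-1))
        return stack_rows(rows)


_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def tokenize(text: str) -> list[str]:
    """Lowercase word tokenizer that keeps hyphenated compounds together."""
    return _TOKEN_RE.findall(text.lower())


class TinyTextEncoder(EncoderAdapter):
    """Hashed bag-of-token embeddings refined by one transformer block."""

    modality = "text"

    def __init__(self, vocab_size: int = 512, d_model: int = 32,
                 embedding_dim: int = 32, n_blocks: int = 1, seed: int = 0):
        super().__init__()
        self.vocab_size = vocab_size
        self.d_model = d_model
        self.embedding_dim = embedding_dim
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 102])
        self.token_embed = self._param(
            0.1 * rng.standard_normal((vocab_size, d_model)), "text.token_embed"
        )
        self._blocks = [TransformerBlock(d_model, rng, f"text.block{i}") for i in range(n_blocks)]
        self.head = self._param(glorot(rng, d_model, embedding_dim), "text.head")

    def blocks(self) -> list[Module]:
        return list(self._blocks)

    def input_parameters(self) -> list[Parameter]:
        return [self.token_embed]

    def head_parameters(self) -> list[Parameter]:
        return [self.head]

    def _token_ids(self, text: str) -> np.ndarray:
        if not isinstance(text, str):
            raise UsageError("text encoder received non-text input (mixed-modality batch?)")
        tokens = tokenize(text) or ["<empty>"]
        return np.array([zlib.crc32(t.encode()) % self.vocab_size for t in tokens])

    def forward(self, texts) -> Tensor:
        if isinstance(texts, str):
            texts = [texts]
        rows = []
        for text in texts:
            x = self.token_embed[self._token_ids(text)]
            for block in self._blocks:
                x = block.forward(x)
            rows.append(linear(x.mean(axis=0, keepdims=True), self.head).reshape(-1))
        return stack_rows(rows)


class EmbeddingAdapter(EncoderAdapter):
    """Trainable trunk over precomputed embedding vectors.

    Wraps a frozen upstream representation (e.g. the synthetic generator's
    vectors, or exported backbone features) with an input projection, a stack
    of residual MLP blocks and a projection head, so the same freeze-policy
    and training machinery applies to stored-embedding experiments.
    """

    def __init__(self, modality: str, input_dim: int, d_model: int = 64,
                 embedding_dim: int = 64, n_blocks: int = 2, seed: int = 0):
        super().__init__()
        self.modality = modality
        self.input_dim = input_dim
        self.embedding_dim = embedding_dim
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 103, zlib.crc32(modality.encode())])
        self.input_proj = self._param(glorot(rng, input_dim, d_model), f"{modality}.input_proj")
        self._blocks = [
            ResidualMLPBlock(d_model, rng, f"{modality}.adapter_block{i}") for i in range(n_blocks)
        ]
        self.head = self._param(glorot(rng, d_model, embedding_dim), f"{modality}.head")

    def blocks(self) -> list[Module]:
        return list(self._blocks)

    def input_parameters(self) -> list[Parameter]:
        return [self.input_proj]

    def head_parameters(self) -> list[Parameter]:
        return [self.head]

    def forward(self, vectors) -> Tensor:
        arr = np.asarray(vectors, dtype=np.float64)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.ndim != 2 or arr.shape[1] != self.input_dim:
            raise UsageError(
                f"expected (n, {self.input_dim}) input vectors, got shape {arr.shape}"
            )
        x = Tensor(arr) @ self.input_proj
        for block in self._blocks:
            x = block.forward(x)
        return linear(x, self.head)


def encode_to_set(encoder: EncoderAdapter, photo_ids: list[str], inputs,
                  modality: str | None = None) -> EmbeddingSet:
    """Run inference on a batch and package the result as an EmbeddingSet."""
    mat = encoder.encode(inputs)
    if mat.shape[0] != len(photo_ids):
        raise UsageError("photo_ids and inputs disagree in length")
    return EmbeddingSet(
        modality=modality or encoder.modality,
        vectors={pid: mat[i] for i, pid in enumerate(photo_ids)},
    )
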