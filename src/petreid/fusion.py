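"""Multimodal fusion heads.

Vision and text embeddings are first projected into a shared space with
separate linear layers; the heads then combine them:

* ``concat`` — concatenation [v ; t] (vision first), length 2*shared_dim;
* ``weighted_text`` — [v ; w*t] with a single trainable scalar w (init 1);
* ``cross_attention`` — one attention layer (4 heads) in which text tokens
  query image patches; the attended token outputs are mean-pooled into a
  single multimodal vector that replaces concatenation;
* ``gated`` — a small MLP with softmax over two outputs turns [v ; t] into
  normalized modality weights (g_img, g_txt), and the fused vector is
  ``g_img * v + g_txt * t`` (length shared_dim).

Heads are deterministic in inference mode and differentiable end-to-end.
Fused vectors are used raw by the triplet term during training and
L2-normalized only at cosine-scoring time (the evaluation module's job).
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concatenate, softmax
from .errors import ConfigError, UsageError
from .nn import MLP, Module, glorot, linear, stack_rows

DEFAULT_SHARED_DIM = 128


def _wrap2d(x, name: str) -> tuple[Tensor, bool]:
    is_tensor = isinstance(x, Tensor)
    t = x if is_tensor else Tensor(np.atleast_2d(np.asarray(x, dtype=np.float64)))
    if t.ndim != 2:
        raise UsageError(f"{name} must be 2-D (n, d), got shape {t.shape}")
    return t, is_tensor


def _check_rows(v: Tensor, t: Tensor) -> None:
    if v.shape[0] != t.shape[0]:
        raise UsageError(f"row mismatch: vision {v.shape[0]} vs text {t.shape[0]}")


class SharedProjection(Module):
    """Separate linear maps taking each modality into the shared space."""

    def __init__(self, vision_dim: int, text_dim: int,
                 shared_dim: int = DEFAULT_SHARED_DIM, seed: int = 0):
        super().__init__()
        self.shared_dim = shared_dim
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 201])
        self.vision_proj = self._param(glorot(rng, vision_dim, shared_dim), "fusion.vision_proj")
        self.text_proj = self._param(glorot(rng, text_dim, shared_dim), "fusion.text_proj")

    def project_vision(self, v: Tensor) -> Tensor:
        return linear(v, self.vision_proj)

    def project_text(self, t: Tensor) -> Tensor:
        return linear(t, self.text_proj)


class TextWeight(Module):
    """Single trainable scalar rescaling the text embedding (initialized to 1)."""

    def __init__(self):
        super().__init__()
        self.w = self._param(np.ones(1), "fusion.text_weight")


class GateHead(Module):
    """MLP [2*shared -> hidden -> 2] + softmax producing modality weights."""

    def __init__(self, shared_dim: int, hidden: int | None = None, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 202])
        self.mlp = MLP(2 * shared_dim, hidden or 2 * shared_dim, 2, rng, name="fusion.gate")
        self._params.extend(self.mlp.parameters())

    def gates(self, v: Tensor, t: Tensor) -> Tensor:
        """(n, 2) softmax weights: column 0 = image, column 1 = text."""
        return softmax(self.mlp.forward(concatenate([v, t], axis=1)), axis=-1)


class CrossAttentionHead(Module):
    """One multi-head attention layer: text queries, image keys/values."""

    def __init__(self, shared_dim: int, n_heads: int = 4, seed: int = 0):
        super().__init__()
        if shared_dim % n_heads:
            raise ConfigError("shared_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.head_dim = shared_dim // n_heads
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 203])
        self.wq = self._param(glorot(rng, shared_dim, shared_dim), "fusion.xattn_wq")
        self.wk = self._param(glorot(rng, shared_dim, shared_dim), "fusion.xattn_wk")
        self.wv = self._param(glorot(rng, shared_dim, shared_dim), "fusion.xattn_wv")
        self.wo = self._param(glorot(rng, shared_dim, shared_dim), "fusion.xattn_wo")

    def forward(self, text_tokens: Tensor, image_patches: Tensor) -> Tensor:
        """(Lt, d) tokens x (Lp, d) patches -> pooled (d,) multimodal vector."""
        if text_tokens.shape[0] == 0 or image_patches.shape[0] == 0:
            raise UsageError("cross-attention requires non-empty token and patch sequences")
        q_all = text_tokens @ self.wq
        k_all = image_patches @ self.wk
        v_all = image_patches @ self.wv
        heads = []
        for h in range(self.n_heads):
            sl = slice(h * self.head_dim, (h + 1) * self.head_dim)
            q, k, v = q_all[:, sl], k_all[:, sl], v_all[:, sl]
            scores = (q @ k.T) * (1.0 / np.sqrt(self.head_dim))
            heads.append(softmax(scores, axis=-1) @ v)
        attended = concatenate(heads, axis=1) @ self.wo
        return attended.mean(axis=0)


def fuse_concat(v, t):
    """[v ; t], vision block first."""
    vt, v_is = _wrap2d(v, "vision")
    tt, t_is = _wrap2d(t, "text")
    _check_rows(vt, tt)
    out = concatenate([vt, tt], axis=1)
    return out if (v_is or t_is) else out.data


def fuse_weighted_text(v, t, weight: TextWeight):
    """[v ; w*t] with the trainable scalar w."""
    vt, v_is = _wrap2d(v, "vision")
    tt, t_is = _wrap2d(t, "text")
    _check_rows(vt, tt)
    out = concatenate([vt, tt * weight.w], axis=1)
    return out if (v_is or t_is) else out.data


def fuse_gated(v, t, gate: GateHead, return_gates: bool = False):
    """Softmax-gated weighted sum g_img*v + g_txt*t."""
    vt, v_is = _wrap2d(v, "vision")
    tt, t_is = _wrap2d(t, "text")
    _check_rows(vt, tt)
    if vt.shape[1] != tt.shape[1]:
        raise UsageError("gated fusion requires both modalities in the shared space")
    g = gate.gates(vt, tt)
    out = vt * g[:, 0:1] + tt * g[:, 1:2]
    if not (v_is or t_is):
        out, g = out.data, g.data
    return (out, g) if return_gates else out


def fuse_cross_attention(image_patches, text_tokens, head: CrossAttentionHead):
    """Single-sample fusion: sequences in the shared space -> pooled vector."""
    pt, p_is = _wrap2d(image_patches, "image_patches")
    tt, t_is = _wrap2d(text_tokens, "text_tokens")
    out = head.forward(tt, pt)
    return out if (p_is or t_is) else out.data


class FusionModel(Module):
    """Kind-dispatching fusion pipeline over raw modality embeddings.

    Projects both modalities into the shared space, applies the configured
    head, and exposes the gate weights of the last gated call for
    inspection. All parameters (projections + head) are trainable.
    """

    def __init__(self, kind: str, vision_dim: int, text_dim: int,
                 shared_dim: int = DEFAULT_SHARED_DIM, gate_hidden: int | None = None,
                 seed: int = 0):
        super().__init__()
        if kind not in ("concat", "cross_attention", "weighted_text", "gated"):
            raise ConfigError(f"unknown fusion kind {kind!r}")
        self.kind = kind
        self.shared_dim = shared_dim
        self.projection = SharedProjection(vision_dim, text_dim, shared_dim, seed)
        self._params.extend(self.projection.parameters())
        self.text_weight: TextWeight | None = None
        self.gate: GateHead | None = None
        self.xattn: CrossAttentionHead | None = None
        if kind == "weighted_text":
            self.text_weight = TextWeight()
            self._params.extend(self.text_weight.parameters())
        elif kind == "gated":
            self.gate = GateHead(shared_dim, gate_hidden, seed)
            self._params.extend(self.gate.parameters())
        elif kind == "cross_attention":
            self.xattn = CrossAttentionHead(shared_dim, seed=seed)
            self._params.extend(self.xattn.parameters())
        self.last_gates: np.ndarray | None = None

    @property
    def output_dim(self) -> int:
        return 2 * self.shared_dim if self.kind in ("concat", "weighted_text") else self.shared_dim

    def fuse(self, vision, text):
        v_raw, v_is = _wrap2d(vision, "vision")
        t_raw, t_is = _wrap2d(text, "text")
        _check_rows(v_raw, t_raw)
        v = self.projection.project_vision(v_raw)
        t = self.projection.project_text(t_raw)
        if self.kind == "concat":
            out = fuse_concat(v, t)
        elif self.kind == "weighted_text":
            out = fuse_weighted_text(v, t, self.text_weight)
        elif self.kind == "gated":
            out, gates = fuse_gated(v, t, self.gate, return_gates=True)
            self.last_gates = gates.data.copy() if isinstance(gates, Tensor) else np.array(gates)
        else:  # cross_attention; single-vector rows act as length-1 sequences
            pooled = [
                self.xattn.forward(t[i : i + 1, :], v[i : i + 1, :])
                for i in range(v.shape[0])
            ]
            out = stack_rows(pooled)
        return out if (v_is or t_is) else out.data
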