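"""Small neural building blocks on top of the autodiff engine.

Everything here operates on 2-D tensors ``(n, d)`` — a batch of vectors or a
sequence of tokens/patches — which keeps the autodiff engine's operator
surface minimal while still expressing transformer blocks and MLP heads.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .autodiff import Parameter, Tensor, concatenate, softmax


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def linear(x: Tensor, weight: Parameter, bias: Parameter | None = None) -> Tensor:
    out = x @ weight
    if bias is not None:
        out = out + bias
    return out


def layer_norm(x: Tensor, gain: Parameter, bias: Parameter, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    centered = x - mu
    var = (centered**2).mean(axis=-1, keepdims=True)
    return centered / (var + eps).sqrt() * gain + bias


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor) -> Tensor:
    """Single-head attention: q (Lq, d), k/v (Lk, d) -> (Lq, d)."""
    d = q.shape[-1]
    scores = (q @ k.T) * (1.0 / np.sqrt(d))
    return softmax(scores, axis=-1) @ v


class Module:
    """Base class: subclasses register parameters via ``_param``."""

    def __init__(self) -> None:
        self._params: list[Parameter] = []

    def _param(self, data: np.ndarray, name: str) -> Parameter:
        p = Parameter(data, name=name)
        self._params.append(p)
        return p

    def parameters(self) -> list[Parameter]:
        return list(self._params)

    def checksums(self) -> dict[str, str]:
        """SHA-256 of every parameter's raw bytes, keyed by name."""
        return {
            p.name: hashlib.sha256(np.ascontiguousarray(p.data).tobytes()).hexdigest()
            for p in self.parameters()
        }


class MLP(Module):
    """One-hidden-layer ReLU MLP."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int,
                 rng: np.random.Generator, name: str = "mlp"):
        super().__init__()
        self.w1 = self._param(glorot(rng, d_in, d_hidden), f"{name}.w1")
        self.b1 = self._param(np.zeros(d_hidden), f"{name}.b1")
        self.w2 = self._param(glorot(rng, d_hidden, d_out), f"{name}.w2")
        self.b2 = self._param(np.zeros(d_out), f"{name}.b2")

    def forward(self, x: Tensor) -> Tensor:
        return linear(linear(x, self.w1, self.b1).relu(), self.w2, self.b2)


class TransformerBlock(Module):
    """Pre-norm transformer layer: self-attention + MLP, both residual."""

    def __init__(self, d_model: int, rng: np.random.Generator, name: str = "block"):
        super().__init__()
        self.wq = self._param(glorot(rng, d_model, d_model), f"{name}.wq")
        self.wk = self._param(glorot(rng, d_model, d_model), f"{name}.wk")
        self.wv = self._param(glorot(rng, d_model, d_model), f"{name}.wv")
        self.wo = self._param(glorot(rng, d_model, d_model), f"{name}.wo")
        self.ln1_g = self._param(np.ones(d_model), f"{name}.ln1_g")
        self.ln1_b = self._param(np.zeros(d_model), f"{name}.ln1_b")
        self.ln2_g = self._param(np.ones(d_model), f"{name}.ln2_g")
        self.ln2_b = self._param(np.zeros(d_model), f"{name}.ln2_b")
        self.w1 = self._param(glorot(rng, d_model, 2 * d_model), f"{name}.ff_w1")
        self.b1 = self._param(np.zeros(2 * d_model), f"{name}.ff_b1")
        self.w2 = self._param(glorot(rng, 2 * d_model, d_model), f"{name}.ff_w2")
        self.b2 = self._param(np.zeros(d_model), f"{name}.ff_b2")

    def forward(self, x: Tensor) -> Tensor:
        h = layer_norm(x, self.ln1_g, self.ln1_b)
        attended = scaled_dot_attention(
            linear(h, self.wq), linear(h, self.wk), linear(h, self.wv)
        )
        x = x + linear(attended, self.wo)
        h = layer_norm(x, self.ln2_g, self.ln2_b)
        return x + linear(linear(h, self.w1, self.b1).relu(), self.w2, self.b2)


class ResidualMLPBlock(Module):
    """Residual feed-forward layer; the 'block' unit of the embedding adapters."""

    def __init__(self, d_model: int, rng: np.random.Generator, name: str = "resblock"):
        super().__init__()
        self.w1 = self._param(glorot(rng, d_model, d_model), f"{name}.w1")
        self.b1 = self._param(np.zeros(d_model), f"{name}.b1")
        self.w2 = self._param(glorot(rng, d_model, d_model), f"{name}.w2")
        self.b2 = self._param(np.zeros(d_model), f"{name}.b2")

    def forward(self, x: Tensor) -> Tensor:
        return x + linear(linear(x, self.w1, self.b1).relu(), self.w2, self.b2)


def stack_rows(rows: list[Tensor]) -> Tensor:
    """Stack 1-D tensors (d,) into (n, d) keeping gradients."""
    return concatenate([r.reshape(1, -1) for r in rows], axis=0)
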