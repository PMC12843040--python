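"""Run configuration.

Defaults reproduce the training recipe used throughout the study: batches of
P = 58 identities x K = 2 photos (116 samples), Adam at a fixed learning rate
of 1e-4 for 10 epochs, with only the final five encoder blocks unfrozen, and
the combined triplet + intra-pair-variance objective
(alpha = 0.45, eps_pos = eps_neg = 0.01, lambda1 = 1.0, lambda2 = 0.5).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

FUSION_KINDS = ("none", "concat", "cross_attention", "weighted_text", "gated")
MINING_KINDS = ("batch_all", "batch_hard")


@dataclass
class LossConfig:
    """Weights and margins of the combined metric-learning objective."""

    margin: float = 0.45
    eps_pos: float = 0.01
    eps_neg: float = 0.01
    lambda1: float = 1.0
    lambda2: float = 0.5
    mining: str = "batch_all"

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ConfigError("margin must be positive")
        if not (0 <= self.eps_pos < 1 and 0 <= self.eps_neg < 1):
            raise ConfigError("eps values must lie in [0, 1)")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ConfigError("lambda weights must be non-negative")
        if self.mining not in MINING_KINDS:
            raise ConfigError(f"mining must be one of {MINING_KINDS}")


@dataclass
class RunConfig:
    """Full training-run configuration."""

    seed: int = 0
    batch_identities: int = 58  # P
    photos_per_identity: int = 2  # K
    learning_rate: float = 1e-4
    epochs: int = 10
    unfrozen_blocks: int = 5
    loss: LossConfig = field(default_factory=LossConfig)
    fusion_kind: str = "none"

    def __post_init__(self) -> None:
        if self.batch_identities < 1 or self.photos_per_identity < 1:
            raise ConfigError("P and K must be positive")
        if self.learning_rate < 0:
            raise ConfigError("learning rate must be non-negative")
        if self.epochs < 1:
            raise ConfigError("epochs must be positive")
        if self.unfrozen_blocks < 0:
            raise ConfigError("unfrozen_blocks must be non-negative")
        if self.fusion_kind not in FUSION_KINDS:
            raise ConfigError(f"fusion_kind must be one of {FUSION_KINDS}")

    @property
    def batch_size(self) -> int:
        return self.batch_identities * self.photos_per_identity

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Short stable hash of the configuration, for log lines and checkpoints."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        loss = data.pop("loss", {})
        return cls(loss=LossConfig(**loss), **data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
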