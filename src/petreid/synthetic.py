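"""Identity-structured synthetic multimodal pet data.

The generator emulates a lost-and-found pet corpus: each identity owns a
categorical attribute vector (coat color, pattern, size, ear shape,
distinctive mark), a templated standardized description, a small toy image
per photo, and per-photo vision/text embeddings.

Embedding model. Every identity has one unit-norm latent prototype per
modality, built from fixed per-attribute-value embeddings plus an
identity-unique direction. A photo's embedding is::

    rho * prototype + (1 - rho) * fresh_direction + sigma * jitter

where ``rho`` is that modality's identity-informativeness, the fresh
direction is a per-photo unit vector independent of identity, and jitter is
isotropic Gaussian measurement noise. ``rho = 0`` makes the modality
statistically independent of identity; ``rho = 1, sigma = 0`` reproduces the
prototype exactly.

Complementarity. The vision prototype sees coat color, pattern, size and ear
shape; the text prototype sees coat color, pattern and the text-exclusive
distinctive mark. The two modalities therefore share some identity evidence
but each carries evidence the other lacks, so a good fusion can beat either
modality alone.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ValidationError
from .records import DatasetManifest, EmbeddingSet, PhotoRecord

COAT_COLORS = ("black", "white", "ginger", "gray", "brown", "cream", "golden", "tricolor")
PATTERNS = ("solid", "striped", "spotted", "patched", "brindle", "tabby")
SIZES = ("small", "medium", "large")
EAR_SHAPES = ("pointed", "floppy", "rounded", "folded")
MARKS = ("ear-notch", "tail-kink", "nose-scar", "freckled-muzzle", "heterochromia", "torn-whisker")

ATTRIBUTE_VOCABULARIES: dict[str, tuple[str, ...]] = {
    "coat_color": COAT_COLORS,
    "pattern": PATTERNS,
    "size": SIZES,
    "ear_shape": EAR_SHAPES,
    "mark": MARKS,
}
VISION_ATTRIBUTES = ("coat_color", "pattern", "size", "ear_shape")
TEXT_ATTRIBUTES = ("coat_color", "pattern", "mark")  # mark is text-exclusive

_DESCRIPTION_TEMPLATE = (
    "A {size} {species} with a {coat_color} {pattern} coat, "
    "{ear_shape} ears, and a distinctive {mark}."
)

# Per-purpose stream keys: changing, say, the photo-count draw must not
# reshuffle identity profiles, so each purpose gets its own child stream.
_STREAM_PROFILES = 11
_STREAM_PHOTOS = 13
_STREAM_NOISE = 17
_STREAM_VOCAB = 19


def _rng(master_seed: int, purpose: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, purpose, *extra])


@dataclass
class SynthConfig:
    """Knobs of the synthetic corpus.

    Photos per identity default to a uniform draw on [2, 10], the range the
    lost-pet listings exhibit; informativeness defaults give moderately
    discriminative but imperfect modalities.
    """

    n_identities: int = 50
    min_photos: int = 2
    max_photos: int = 10
    vision_dim: int = 64
    text_dim: int = 32
    vision_informativeness: float = 0.6  # rho_v
    text_informativeness: float = 0.6  # rho_t
    noise_scale: float = 0.1  # sigma
    identity_component_weight: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_identities < 2:
            raise ConfigError("verification needs negatives: n_identities must be >= 2")
        if not (1 <= self.min_photos <= self.max_photos):
            raise ConfigError("need 1 <= min_photos <= max_photos")
        if self.vision_dim < 1 or self.text_dim < 1:
            raise ConfigError("embedding dims must be positive")
        for name in ("vision_informativeness", "text_informativeness"):
            rho = getattr(self, name)
            if not (0.0 <= rho <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.noise_scale < 0:
            raise ConfigError("noise_scale must be non-negative")


@dataclass
class IdentityProfile:
    """One synthetic animal: attributes plus per-modality latent prototypes."""

    identity_id: str
    species: str
    attributes: dict[str, str]
    prototypes: dict[str, np.ndarray] = field(default_factory=dict)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _attribute_embedding(attr: str, value: str, modality: str, dim: int, seed: int) -> np.ndarray:
    """Fixed unit embedding of one attribute value, stable across calls."""
    key = zlib.crc32(f"{modality}|{attr}|{value}".encode()) & 0x7FFFFFFF
    rng = _rng(seed, _STREAM_VOCAB, key)
    return _unit(rng.normal(size=dim))


def generate_profiles(config: SynthConfig) -> list[IdentityProfile]:
    rng = _rng(config.seed, _STREAM_PROFILES)
    profiles = []
    for i in range(config.n_identities):
        attrs = {name: str(rng.choice(vocab)) for name, vocab in ATTRIBUTE_VOCABULARIES.items()}
        species = str(rng.choice(["cat", "dog"]))
        prototypes = {}
        for modality, dim, attr_names in (
            ("vision", config.vision_dim, VISION_ATTRIBUTES),
            ("text", config.text_dim, TEXT_ATTRIBUTES),
        ):
            attr_part = np.mean(
                [
                    _attribute_embedding(a, attrs[a], modality, dim, config.seed)
                    for a in attr_names
                ],
                axis=0,
            )
            unique = _unit(rng.normal(size=dim))
            prototypes[modality] = _unit(
                attr_part + config.identity_component_weight * unique
            )
        profiles.append(
            IdentityProfile(
                identity_id=f"id{i:04d}",
                species=species,
                attributes=attrs,
                prototypes=prototypes,
            )
        )
    return profiles


def render_description(profile: IdentityProfile) -> str:
    """Deterministic standardized caption naming species and all attributes once."""
    missing = [k for k in ATTRIBUTE_VOCABULARIES if k not in profile.attributes]
    if missing:
        raise ValidationError(f"profile {profile.identity_id} lacks attribute(s): {missing}")
    return _DESCRIPTION_TEMPLATE.format(species=profile.species, **profile.attributes)


_COLOR_RGB = {
    "black": (30, 30, 30),
    "white": (235, 235, 235),
    "ginger": (220, 120, 40),
    "gray": (128, 128, 128),
    "brown": (120, 72, 30),
    "cream": (240, 220, 180),
    "golden": (218, 170, 60),
    "tricolor": (200, 120, 160),
}


def render_toy_image(profile: IdentityProfile, photo_index: int, seed: int,
                     size: int = 64) -> np.ndarray:
    """Tiny raster whose colors/shapes encode the attributes, with photo jitter.

    The coat color fills a central blob whose radius encodes body size, the
    pattern adds stripes or spots, and the ear shape adds top markers; jitter
    is a deterministic per-photo translation and brightness change.
    """
    if set(ATTRIBUTE_VOCABULARIES) - set(profile.attributes):
        raise ValidationError(f"profile {profile.identity_id} has an incomplete attribute vector")
    key = zlib.crc32(profile.identity_id.encode()) & 0x7FFFFFFF
    rng = _rng(seed, _STREAM_PHOTOS, key, photo_index)

    img = np.full((size, size, 3), 64, dtype=np.float64)  # neutral background
    color = np.array(_COLOR_RGB[profile.attributes["coat_color"]], dtype=np.float64)
    radius = {"small": size // 6, "medium": size // 4, "large": size // 3}[
        profile.attributes["size"]
    ]
    dy, dx = rng.integers(-4, 5, size=2)  # nuisance translation
    cy, cx = size // 2 + dy, size // 2 + dx
    yy, xx = np.mgrid[0:size, 0:size]
    blob = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    img[blob] = color

    pattern = profile.attributes["pattern"]
    accent = 255.0 - color  # complementary accent color
    if pattern == "striped" or pattern == "tabby":
        stripes = blob & ((yy - cy) % 8 < 3)
        img[stripes] = accent
    elif pattern == "spotted" or pattern == "brindle":
        spots = blob & (((yy - cy) % 10 < 3) & ((xx - cx) % 10 < 3))
        img[spots] = accent
    elif pattern == "patched":
        img[blob & (xx > cx)] = 0.5 * color + 0.5 * accent
    # "solid": no accent

    ear_row = max(cy - radius - 3, 0)
    ear_code = EAR_SHAPES.index(profile.attributes["ear_shape"])
    img[ear_row : ear_row + 2, cx - 2 * (ear_code + 1) : cx + 2 * (ear_code + 1)] = color

    brightness = rng.uniform(0.8, 1.2)  # nuisance illumination
    return np.clip(img * brightness, 0, 255).astype(np.uint8)


def generate_dataset(
    config: SynthConfig,
) -> tuple[DatasetManifest, EmbeddingSet, EmbeddingSet]:
    """Build a manifest plus per-photo vision and text embedding stores."""
    profiles = generate_profiles(config)
    count_rng = _rng(config.seed, _STREAM_PHOTOS)
    records: list[PhotoRecord] = []
    vision: dict[str, np.ndarray] = {}
    text: dict[str, np.ndarray] = {}
    for profile in profiles:
        n_photos = int(count_rng.integers(config.min_photos, config.max_photos + 1))
        description = render_description(profile)
        key = zlib.crc32(profile.identity_id.encode()) & 0x7FFFFFFF
        noise_rng = _rng(config.seed, _STREAM_NOISE, key)
        for j in range(n_photos):
            photo_id = f"{profile.identity_id}_p{j}"
            records.append(
                PhotoRecord(
                    photo_id=photo_id,
                    identity_id=profile.identity_id,
                    species=profile.species,
                    description=description,
                )
            )
            for modality, dim, rho, store in (
                ("vision", config.vision_dim, config.vision_informativeness, vision),
                ("text", config.text_dim, config.text_informativeness, text),
            ):
                fresh = _unit(noise_rng.normal(size=dim))
                jitter = config.noise_scale * noise_rng.normal(size=dim)
                store[photo_id] = (
                    rho * profile.prototypes[modality] + (1.0 - rho) * fresh + jitter
                )
    manifest = DatasetManifest(records=records, split_tag="train")
    return (
        manifest,
        EmbeddingSet(modality="vision", vectors=vision),
        EmbeddingSet(modality="text", vectors=text),
    )
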