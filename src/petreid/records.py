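"""Canonical data types and portable I/O.

A *manifest* lists one photograph per row: photo id, identity label, species,
an optional image path and an optional free-text description. Manifests travel
as UTF-8 CSV with a header row, or as JSON-lines with the same field names.

Embeddings are persisted as a platform-independent binary array (``.npy``)
plus a JSON sidecar recording the photo-id order, the modality tag and the
vector dimension, so the store can be read from any language with an
npy reader and a JSON parser.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import (
    CorruptionError,
    EmptyInputError,
    FormatError,
    ValidationError,
)

SPECIES = ("cat", "dog", "other")
MODALITIES = ("vision", "text", "fused")
MANIFEST_COLUMNS = ("photo_id", "identity_id", "species", "image_ref", "description")


@dataclass(frozen=True)
class PhotoRecord:
    """One photograph of one individual animal."""

    photo_id: str
    identity_id: str
    species: str = "other"
    image_ref: str | None = None
    description: str | None = None

    def __post_init__(self) -> None:
        if not self.photo_id:
            raise ValidationError("photo_id must be non-empty")
        if not self.identity_id:
            raise ValidationError("identity_id must be non-empty")
        if self.species not in SPECIES:
            raise ValidationError(
                f"species {self.species!r} not one of {SPECIES}"
            )
        if self.image_ref is None and self.description is None:
            raise ValidationError(
                f"record {self.photo_id!r} carries neither an image_ref nor a description"
            )


@dataclass
class DatasetManifest:
    """An ordered collection of photo records with a train/eval split tag."""

    records: list[PhotoRecord]
    split_tag: str = "train"

    def __post_init__(self) -> None:
        if self.split_tag not in ("train", "eval"):
            raise ValidationError(f"split_tag must be 'train' or 'eval', got {self.split_tag!r}")
        seen: set[str] = set()
        for rec in self.records:
            if rec.photo_id in seen:
                raise ValidationError(f"duplicate photo_id {rec.photo_id!r} in manifest")
            seen.add(rec.photo_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def identities(self) -> list[str]:
        """Distinct identity labels in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for rec in self.records:
            if rec.identity_id not in seen:
                seen.add(rec.identity_id)
                out.append(rec.identity_id)
        return out

    def photos_by_identity(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for rec in self.records:
            groups.setdefault(rec.identity_id, []).append(rec.photo_id)
        return groups

    def record_by_photo(self) -> dict[str, PhotoRecord]:
        return {rec.photo_id: rec for rec in self.records}


def check_identity_disjoint(train: DatasetManifest, eval_: DatasetManifest) -> None:
    """Enforce stratified identity separation between the two splits.

    Raises ValidationError naming every offending identity.
    """
    overlap = sorted(set(train.identities) & set(eval_.identities))
    if overlap:
        raise ValidationError(
            "train and eval manifests share identities: " + ", ".join(overlap)
        )


def _records_from_frame(df: pd.DataFrame) -> list[PhotoRecord]:
    missing = [c for c in ("photo_id", "identity_id") if c not in df.columns]
    if missing:
        raise FormatError(f"manifest is missing required column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()

        def opt(key: str) -> str | None:
            v = d.get(key)
            if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
                return None
            return str(v)

        records.append(
            PhotoRecord(
                photo_id=str(d["photo_id"]),
                identity_id=str(d["identity_id"]),
                species=str(d.get("species") or "other"),
                image_ref=opt("image_ref"),
                description=opt("description"),
            )
        )
    return records


def read_manifest(path: str | Path, split_tag: str = "train") -> DatasetManifest:
    """Read a CSV or JSON-lines manifest and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise EmptyInputError(f"manifest file {path} is empty")
    if path.suffix.lower() in (".jsonl", ".ndjson", ".json"):
        df = pd.read_json(path, lines=True, dtype=str)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        raise EmptyInputError(f"manifest {path} contains no records")
    return DatasetManifest(records=_records_from_frame(df), split_tag=split_tag)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    """Write a manifest; dialect chosen from the file suffix (CSV default)."""
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "photo_id": r.photo_id,
                "identity_id": r.identity_id,
                "species": r.species,
                "image_ref": r.image_ref or "",
                "description": r.description or "",
            }
            for r in manifest.records
        ],
        columns=list(MANIFEST_COLUMNS),
    )
    if path.suffix.lower() in (".jsonl", ".ndjson"):
        df.to_json(path, orient="records", lines=True, force_ascii=False)
    else:
        df.to_csv(path, index=False)


def summarize_manifest(manifest: DatasetManifest) -> dict[str, float]:
    """Per-identity photo-count statistics: min, max, mean, median, std.

    ``std`` is the sample standard deviation (n-1 denominator); with a single
    identity it is reported as 0.
    """
    if len(manifest) == 0:
        raise EmptyInputError("cannot summarize an empty manifest")
    counts = np.array([len(v) for v in manifest.photos_by_identity().values()], dtype=float)
    std = float(counts.std(ddof=1)) if counts.size > 1 else 0.0
    return {
        "n_identities": int(counts.size),
        "n_photos": int(counts.sum()),
        "min": float(counts.min()),
        "max": float(counts.max()),
        "mean": float(counts.mean()),
        "median": float(np.median(counts)),
        "std": std,
    }


@dataclass
class EmbeddingSet:
    """Modality-tagged fixed-dimension vectors keyed by photo id."""

    modality: str
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality {self.modality!r} not one of {MODALITIES}")
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValidationError(f"inconsistent vector shapes: {sorted(dims)}")
        for pid, v in self.vectors.items():
            if v.ndim != 1:
                raise ValidationError(f"vector for {pid!r} is not 1-D")
            if not np.all(np.isfinite(v)):
                raise ValidationError(f"non-finite components in vector for {pid!r}")

    @property
    def dim(self) -> int:
        if not self.vectors:
            raise EmptyInputError("embedding set is empty")
        return next(iter(self.vectors.values())).shape[0]

    def __len__(self) -> int:
        return len(self.vectors)

    def __getitem__(self, photo_id: str) -> np.ndarray:
        return self.vectors[photo_id]

    def matrix(self, photo_ids: Iterable[str] | None = None) -> np.ndarray:
        ids = list(photo_ids) if photo_ids is not None else list(self.vectors)
        return np.stack([self.vectors[p] for p in ids])

    def check_against(self, manifest: DatasetManifest) -> None:
        known = {r.photo_id for r in manifest.records}
        unknown = sorted(set(self.vectors) - known)
        if unknown:
            raise ValidationError(f"embedding keys not in manifest: {unknown[:5]}...")


def save_embeddings(embeddings: EmbeddingSet, path: str | Path) -> None:
    """Persist to ``<path>.npy`` (float64 matrix) + ``<path>.json`` sidecar."""
    path = Path(path)
    ids = list(embeddings.vectors)
    mat = embeddings.matrix(ids).astype(np.float64) if ids else np.zeros((0, 0))
    np.save(path.with_suffix(".npy"), mat)
    sidecar = {
        "modality": embeddings.modality,
        "dim": int(mat.shape[1]) if ids else 0,
        "photo_ids": ids,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_embeddings(path: str | Path) -> EmbeddingSet:
    path = Path(path)
    npy, sidecar_path = path.with_suffix(".npy"), path.with_suffix(".json")
    if not npy.exists() or not sidecar_path.exists():
        raise CorruptionError(f"embedding store {path} is missing its array or sidecar")
    try:
        sidecar = json.loads(sidecar_path.read_text())
        mat = np.load(npy)
    except Exception as exc:  # noqa: BLE001 - any parse failure is corruption here
        raise CorruptionError(f"cannot read embedding store {path}: {exc}") from exc
    ids: list[str] = sidecar["photo_ids"]
    if mat.shape[0] != len(ids):
        raise CorruptionError(
            f"array rows ({mat.shape[0]}) disagree with sidecar photo_ids ({len(ids)})"
        )
    if ids and mat.shape[1] != sidecar["dim"]:
        raise CorruptionError(
            f"array dim ({mat.shape[1]}) disagrees with sidecar dim ({sidecar['dim']})"
        )
    return EmbeddingSet(
        modality=sidecar["modality"],
        vectors={pid: mat[i].copy() for i, pid in enumerate(ids)},
    )


def log_line(event: str, **fields: object) -> str:
    """Structured ``key=value`` log line; returned (and printable) for testability."""
    parts = [f"event={event}"] + [f"{k}={v}" for k, v in fields.items()]
    line = " ".join(parts)
    print(line)
    return line
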