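"""t-SNE inspection of embedding spaces.

The protocol: keep only the top 30 most frequent identities (ties at the
boundary broken lexicographically by label), cap each at 100 samples
(uniform, seeded), then project to 2-D with t-SNE at perplexity 30. Panels
of a multi-configuration figure share axis limits and grid lines so cluster
structure can be compared directly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from sklearn.manifold import TSNE

from .errors import ConfigError, EmptyInputError


@dataclass
class TsneConfig:
    top_classes: int = 30
    per_class_cap: int = 100
    perplexity: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_classes < 1 or self.per_class_cap < 1:
            raise ConfigError("top_classes and per_class_cap must be positive")
        if self.perplexity <= 0:
            raise ConfigError("perplexity must be positive")


def filter_for_tsne(embeddings: np.ndarray, labels,
                    config: TsneConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Keep the most frequent classes, then cap samples per class."""
    config = config or TsneConfig()
    embeddings = np.asarray(embeddings)
    labels = np.asarray(labels)
    if embeddings.shape[0] == 0:
        raise EmptyInputError("no embeddings to filter")
    counts = Counter(labels.tolist())
    # Most frequent first; frequency ties broken lexicographically by label.
    ranked = sorted(counts, key=lambda lab: (-counts[lab], lab))
    keep_classes = set(ranked[: config.top_classes])
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 41])
    keep_idx: list[int] = []
    for lab in sorted(keep_classes):
        idx = np.flatnonzero(labels == lab)
        if len(idx) > config.per_class_cap:
            idx = np.sort(rng.choice(idx, size=config.per_class_cap, replace=False))
        keep_idx.extend(idx.tolist())
    keep_idx = sorted(keep_idx)
    return embeddings[keep_idx], labels[keep_idx]


def tsne_coordinates(embeddings: np.ndarray, config: TsneConfig | None = None) -> np.ndarray:
    """Deterministic 2-D t-SNE projection (PCA init, pinned learning rate)."""
    config = config or TsneConfig()
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.shape[0] < 2:
        raise EmptyInputError("t-SNE needs at least 2 samples")
    if config.perplexity >= embeddings.shape[0]:
        raise ConfigError(
            f"perplexity ({config.perplexity}) must be < sample count ({embeddings.shape[0]})"
        )
    tsne = TSNE(
        n_components=2, perplexity=config.perplexity, random_state=config.seed,
        init="pca", learning_rate=200.0,
    )
    return tsne.fit_transform(embeddings)


def tsne_plot(embeddings: np.ndarray, labels, config: TsneConfig | None = None,
              ax: plt.Axes | None = None) -> tuple[np.ndarray, plt.Figure]:
    """Project and scatter, one color per class, with grid lines."""
    config = config or TsneConfig()
    coords = tsne_coordinates(embeddings, config)
    labels = np.asarray(labels)
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 6))
    else:
        fig = ax.figure
    classes = sorted(set(labels.tolist()))
    cmap = plt.get_cmap("tab20" if len(classes) <= 20 else "hsv")
    for i, lab in enumerate(classes):
        mask = labels == lab
        ax.scatter(coords[mask, 0], coords[mask, 1], s=8,
                   color=cmap(i / max(1, len(classes))), label=str(lab))
    ax.grid(True, alpha=0.4)
    return coords, fig


def tsne_panel(embedding_sets: dict[str, tuple[np.ndarray, np.ndarray]],
               config: TsneConfig | None = None) -> plt.Figure:
    """One subplot per configuration with shared axis limits and grids."""
    config = config or TsneConfig()
    n = len(embedding_sets)
    if n == 0:
        raise EmptyInputError("no embedding sets to plot")
    ncols = min(3, n)
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(5 * ncols, 5 * nrows), squeeze=False)
    all_coords = []
    for ax, (name, (emb, labels)) in zip(axes.ravel(), embedding_sets.items()):
        coords, _ = tsne_plot(emb, labels, config, ax=ax)
        ax.set_title(name)
        all_coords.append(coords)
    stacked = np.vstack(all_coords)
    xlim = (stacked[:, 0].min(), stacked[:, 0].max())
    ylim = (stacked[:, 1].min(), stacked[:, 1].max())
    for ax in axes.ravel()[:n]:
        ax.set_xlim(*xlim)
        ax.set_ylim(*ylim)
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    return fig
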