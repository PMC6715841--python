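"""Population-level 2D views of hyperspectrum catalogs (PCA, t-SNE).

Within- and between-population variability of single-cell fluorescence
signatures is visualized by reducing the 192-dimensional feature
vectors to two components.  A silhouette-based separation score makes
cluster formation quantitatively testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.metrics import silhouette_score

from .catalog import HyperspectrumCatalog, merge_catalogs
from .spectra import feature_matrix


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (n, 2)
    method: str
    params: dict
    cell_ids: np.ndarray
    labels: list[str] | None = None
    explained_variance_ratio: np.ndarray | None = None  # PCA only


def _pooled_features(
    catalogs: HyperspectrumCatalog | list[HyperspectrumCatalog],
    feature_mode: str,
    normalization: str,
):
    if isinstance(catalogs, HyperspectrumCatalog):
        pooled = catalogs
    elif len(catalogs) == 1:
        pooled = catalogs[0]
    else:
        pooled = merge_catalogs(list(catalogs))
    pooled = pooled.sorted_by_id()  # fixed input order => reproducible embeddings
    X, labels = feature_matrix(pooled, feature_mode, normalization)
    ids = np.array([e.cell_id for e in pooled.entries])
    return X, labels, ids


def run_pca(
    catalogs,
    feature_mode: str = "raw",
    normalization: str = "max1",
) -> EmbeddingResult:
    """First two principal components of the pooled feature vectors.

    Component signs are fixed by making each component's largest-
    magnitude loading positive, so results are deterministic.
    """
    X, labels, ids = _pooled_features(catalogs, feature_mode, normalization)
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 cells")
    n_comp = min(2, len(X), X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    coords = pca.fit_transform(X)
    for j in range(n_comp):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, j] *= -1.0
    if n_comp < 2:
        coords = np.hstack([coords, np.zeros((len(X), 2 - n_comp))])
    return EmbeddingResult(
        coords, "pca",
        {"n_components": 2, "feature_mode": feature_mode, "normalization": normalization},
        ids, labels, pca.explained_variance_ratio_,
    )


def run_tsne(
    catalogs,
    perplexity: float = 30.0,
    seed: int = 0,
    feature_mode: str = "raw",
    normalization: str = "max1",
    n_iter: int = 1000,
) -> EmbeddingResult:
    """t-SNE embedding of the pooled feature vectors.

    PCA initialization and a fixed seed keep runs reproducible; inputs
    are sorted by cell id so the embedding does not depend on catalog
    order.
    """
    X, labels, ids = _pooled_features(catalogs, feature_mode, normalization)
    if len(X) <= 3 * perplexity:
        raise ValueError(
            f"t-SNE needs more than 3 x perplexity = {3 * perplexity:.0f} cells, got {len(X)}"
        )
    tsne = TSNE(
        n_components=2, perplexity=perplexity, init="pca",
        random_state=seed, max_iter=n_iter,
    )
    coords = tsne.fit_transform(X)
    return EmbeddingResult(
        coords, "tsne",
        {"perplexity": perplexity, "seed": seed, "n_iter": n_iter,
         "feature_mode": feature_mode, "normalization": normalization},
        ids, labels,
    )


def separation_score(coords: np.ndarray, labels) -> float:
    """Mean silhouette (Euclidean) of the embedded points; in [-1, 1]."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("separation score needs at least 2 distinct labels")
    return float(silhouette_score(np.asarray(coords, dtype=float), labels, metric="euclidean"))
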