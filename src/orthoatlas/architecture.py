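"""Tissue-architecture analysis: PCA over tissues, tissue clustering, and
category-specific gene filters.

Tissue categories are the observations (rows) and genes the variables, so
component scores place tissues in a low-dimensional map where organ systems
with related physiology cluster together; in a conserved compendium the
first component separates the central-nervous-system block from the rest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .prep import TissueMetaProfileMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaProjection:
    """PCA of a tissues x genes matrix.

    ``scores``: tissues x components; ``loadings``: genes x components;
    ``explained_variance_ratio`` non-increasing.  Component signs are fixed
    by forcing the largest-magnitude loading of each component positive, so
    repeated runs are reproducible bit-for-bit.
    """

    species: str
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions must be non-increasing, sum <= 1")


def run_pca(
    meta: TissueMetaProfileMatrix, n_components: int | None = None
) -> PcaProjection:
    """Centered PCA with tissues as observations and genes as variables."""
    x = meta.values.to_numpy(dtype=float).T  # tissues x genes
    n_obs, n_var = x.shape
    max_comp = min(n_obs, n_var)
    if n_components is None:
        n_components = min(max_comp, 10)
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds min(n_tissues, n_genes)={max_comp}"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    loadings = pca.components_.T  # genes x components
    for j in range(n_components):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(n_components)]
    return PcaProjection(
        species=meta.species,
        scores=pd.DataFrame(scores, index=meta.values.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=meta.values.index, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
    )


@dataclass
class TissueTree:
    """Complete-linkage tree over tissues with d = 1 - Pearson r."""

    species: str
    labels: list
    linkage_matrix: np.ndarray
    dropped: list

    def to_newick(self) -> str:
        return linkage_to_newick(self.linkage_matrix, self.labels)


def correlation_distance_matrix(values: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    """1 - Pearson r between columns; constant columns dropped with warning."""
    sd = values.std(axis=0, ddof=0)
    constant = sd[sd == 0.0].index.tolist()
    if constant:
        logger.warning("dropping constant columns (undefined correlation): %s", constant)
    kept = [c for c in values.columns if c not in set(constant)]
    r = np.corrcoef(values[kept].to_numpy(dtype=float).T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return d, kept, constant


def cluster_tissues(meta: TissueMetaProfileMatrix) -> TissueTree:
    """Agglomerative complete linkage on d(a, b) = 1 - r(a, b)."""
    if meta.values.shape[1] < 2:
        raise ValueError("clustering needs >= 2 tissues")
    d, kept, dropped = correlation_distance_matrix(meta.values)
    z = linkage(squareform(d, checks=False), method="complete")
    return TissueTree(
        species=meta.species, labels=kept, linkage_matrix=z, dropped=dropped
    )


def linkage_to_newick(z: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    root = to_tree(z)

    def fmt(node, parent_height: float) -> str:
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:.10g}"
        length = max(parent_height - node.dist, 0.0)
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = fmt(root.left, root.dist)
    right = fmt(root.right, root.dist)
    return f"({left},{right});"


def find_category_specific_genes(
    meta: TissueMetaProfileMatrix,
    target_category: str,
    on_threshold: float,
    off_threshold: float,
) -> list:
    """Genes on in the target category and off in *every* other category.

    Thresholds are on the scale of ``meta`` (log2 expression, log-ratios or
    z-scores, whichever matrix is passed in).
    """
    if on_threshold <= off_threshold:
        raise ValueError("on_threshold must exceed off_threshold")
    if target_category not in meta.values.columns:
        raise KeyError(f"category {target_category!r} not in matrix")
    target = meta.values[target_category]
    others = meta.values.drop(columns=[target_category])
    mask = (target >= on_threshold) & (others.le(off_threshold).all(axis=1))
    return list(meta.values.index[mask])


def architecture_correlation(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame, n_components: int = 2
) -> float:
    """Similarity of two species' tissue maps on the first components.

    Components are sign-aligned pairwise (PCA signs are arbitrary), then the
    Pearson correlation of the concatenated score vectors is returned —
    a Procrustes-style scalar summary of how congruent the architectures are.
    """
    common = scores_a.index.intersection(scores_b.index)
    a = scores_a.loc[common].iloc[:, :n_components].to_numpy(dtype=float)
    b = scores_b.loc[common].iloc[:, :n_components].to_numpy(dtype=float).copy()
    for j in range(a.shape[1]):
        if np.dot(a[:, j], b[:, j]) < 0:
            b[:, j] *= -1.0
    av, bv = a.ravel(), b.ravel()
    return float(np.corrcoef(av, bv)[0, 1])
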