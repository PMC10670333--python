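"""Sample-structure summaries: Euclidean distances on VST-scale
expression, complete-linkage hierarchical clustering (with Newick
export), and PCA over the most variable genes."""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
from sklearn.decomposition import PCA

from .datatypes import ValidationError


def euclidean_distances(expr: pd.DataFrame) -> pd.DataFrame:
    """Symmetric sample x sample Euclidean distance matrix of a
    genes x samples expression frame."""
    if expr.shape[1] < 2:
        raise ValidationError("need >= 2 samples")
    X = expr.to_numpy(dtype=float).T
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(X, metric="euclidean"))
    return pd.DataFrame(d, index=expr.columns, columns=expr.columns)


def hclust_complete(dist: pd.DataFrame) -> np.ndarray:
    """Complete-linkage agglomerative clustering of a distance matrix.

    Returns the scipy linkage matrix (merge heights are non-decreasing
    for complete linkage).
    """
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-9):
        raise ValidationError("distance matrix must be square and symmetric")
    condensed = scipy.spatial.distance.squareform(d, checks=False)
    return scipy.cluster.hierarchy.linkage(condensed, method="complete")


def linkage_to_newick(linkage: np.ndarray, leaves: list[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths
    derived from merge heights."""
    n = len(leaves)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: leaves[i] for i in range(n)}
    for m, (a, b, h, _) in enumerate(linkage):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        node_id = n + m
        nodes[node_id] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[node_id] = h
    return nodes[n + len(linkage) - 1] + ";"


def pca_scores(
    expr: pd.DataFrame, n_components: int = 2, n_top_genes: int = 500
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene-centred PCA of samples over the most variable genes.

    Component signs are fixed by making each component's
    largest-magnitude gene loading positive, so scores are reproducible
    across linear-algebra backends.  Returns (scores: samples x PCs,
    variance-explained fractions).
    """
    n_samples = expr.shape[1]
    if n_samples < n_components + 1:
        raise ValidationError("need more samples than components")
    var = expr.var(axis=1)
    if float(var.max()) == 0.0:
        raise ValidationError("constant expression matrix; PCA degenerate")
    top = var.sort_values(ascending=False, kind="stable").index[:n_top_genes]
    X = expr.loc[top].to_numpy(dtype=float).T  # samples x genes
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    for c in range(n_components):
        load = model.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, c] *= -1.0
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=expr.columns, columns=cols), model.explained_variance_ratio_
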