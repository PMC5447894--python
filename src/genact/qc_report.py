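"""Sample-level QC views: distances, classical MDS, hierarchical
clustering with Newick export, and row-relative expression tables."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "sample_distances",
    "classical_mds",
    "hierarchical_clustering",
    "linkage_to_newick",
    "relative_heatmap",
]


def sample_distances(log2cpm: pd.DataFrame, n_top_genes: int = 500) -> pd.DataFrame:
    """Euclidean sample x sample distances over the most variable genes."""
    if n_top_genes < 2:
        raise ValueError("n_top_genes must be >= 2")
    x = log2cpm.to_numpy(dtype=float)
    if x.shape[0] < n_top_genes:
        warnings.warn(
            f"only {x.shape[0]} genes available, fewer than n_top_genes={n_top_genes}; using all",
            stacklevel=2,
        )
        n_top_genes = x.shape[0]
    v = x.var(axis=1)
    top = np.argsort(-v, kind="stable")[:n_top_genes]
    sub = x[top].T  # samples x genes
    diff = sub[:, None, :] - sub[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=log2cpm.columns, columns=log2cpm.columns)


def classical_mds(d: pd.DataFrame, k: int = 2) -> pd.DataFrame:
    """Torgerson scaling: double-center -B = -0.5 J D^2 J, top-k eigenpairs.

    Axes are ordered by eigenvalue and sign-fixed so the largest-magnitude
    coordinate on each axis is positive.
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    n = dm.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    if not np.allclose(dm, dm.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (dm ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(-vals)
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs[:, :k] * np.sqrt(np.maximum(vals[:k], 0.0))
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    labels = d.index if isinstance(d, pd.DataFrame) else range(n)
    return pd.DataFrame(coords, index=labels, columns=[f"dim{j + 1}" for j in range(k)])


def hierarchical_clustering(d: pd.DataFrame, linkage: str = "average") -> np.ndarray:
    """Agglomerative merge tree (scipy linkage format) from a distance
    matrix; ``average`` or ``complete`` linkage."""
    if linkage not in ("average", "complete"):
        raise ValueError("linkage must be 'average' or 'complete'")
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, dtype=float)
    if dm.shape[0] < 2:
        raise ValueError("need at least two samples")
    cond = squareform(dm, checks=False)
    return hierarchy.linkage(cond, method=linkage)


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(Z)
    labels = list(labels)

    def walk(node, parent_height):
        if node.is_leaf():
            return f"{labels[node.id]}:{parent_height:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{max(parent_height - node.dist, 0.0):g}"

    return f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)});"


def relative_heatmap(values: pd.DataFrame) -> pd.DataFrame:
    """Each row divided by its maximum, so every gene peaks at 1 in its most
    prominent column.  Rows must be non-negative; all-zero rows come back as
    NaN (undefined), never 0/0."""
    x = values.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("expression values must be non-negative")
    row_max = x.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = x / row_max[:, None]
    out[row_max == 0, :] = np.nan
    return pd.DataFrame(out, index=values.index, columns=values.columns)
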