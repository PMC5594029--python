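"""Unsupervised structure: complete-linkage clustering and PCA.

Both operations work on whatever value grid they are given; the usual
pre-transform for lipid profiles (log2 of mol% followed by per-lipid mean
centring) is provided as :func:`log2_center` and applied by the CLI, not
baked into the operations themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import squareform

from .matrix import LipidomeMatrix

__all__ = [
    "ClusterTree",
    "PcaResult",
    "log2_center",
    "hierarchical_cluster",
    "pca",
    "mean_pairwise_correlation",
]


def _as_frame(matrix: Union[LipidomeMatrix, pd.DataFrame]) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, LipidomeMatrix) else matrix


def log2_center(matrix: Union[LipidomeMatrix, pd.DataFrame]) -> pd.DataFrame:
    """log2-transform and mean-centre each lipid column."""
    data = _as_frame(matrix)
    logged = np.log2(data)
    return logged - logged.mean(axis=0)


@dataclass
class ClusterTree:
    """Agglomerative merge tree in SciPy linkage form.

    ``linkage`` is the (n-1) x 4 merge table; ``labels`` names the leaves in
    input order.  Merge heights are non-decreasing (complete linkage is
    monotone), and cophenetic distances dominate the original pairwise
    distances.
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[str]:
        """Leaf labels in dendrogram order."""
        return [self.labels[i] for i in sch.leaves_list(self.linkage)]

    def cophenetic_matrix(self) -> pd.DataFrame:
        dense = squareform(sch.cophenet(self.linkage))
        return pd.DataFrame(dense, index=self.labels, columns=self.labels)

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster assignment for a given number of clusters."""
        flat = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(flat, index=self.labels)

    def to_newick(self) -> str:
        """Newick serialization with branch lengths derived from merge
        heights (child branch = parent height - child height)."""
        root = sch.to_tree(self.linkage)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{_escape(self.labels[node.id])}:{length:g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        left = render(root.left, root.dist)
        right = render(root.right, root.dist)
        return f"({left},{right});"


def _escape(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def hierarchical_cluster(
    matrix: Union[LipidomeMatrix, pd.DataFrame], axis: str = "samples"
) -> ClusterTree:
    """Complete-linkage agglomeration on Euclidean distances.

    ``axis`` selects whether samples (rows) or lipids (columns) are
    clustered.  The clustered axis must be complete (no missing values);
    ties are broken deterministically by input order (SciPy's behaviour).
    """
    data = _as_frame(matrix)
    if axis == "lipids":
        data = data.T
    elif axis != "samples":
        raise ValueError(f"axis must be 'samples' or 'lipids', got {axis!r}")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    if data.isna().any().any():
        raise ValueError("matrix has missing values on the clustered axis")
    z = sch.linkage(data.to_numpy(dtype=float), method="complete", metric="euclidean")
    return ClusterTree(linkage=z, labels=[str(i) for i in data.index])


@dataclass
class PcaResult:
    """Principal components of a value grid.

    ``scores`` are per-sample coordinates, ``loadings`` per-variable unit
    directions, ``explained_variance`` the per-component variances (these
    are non-increasing and sum to the total variance of the centred input).
    The sign convention makes the largest-magnitude loading of each
    component positive.
    """

    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance: np.ndarray

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.explained_variance.sum()
        return self.explained_variance / total if total > 0 else self.explained_variance

    def reconstruct(self) -> pd.DataFrame:
        """Centred (and scaled, if requested at fit) input rebuilt from all
        components."""
        values = self.scores.to_numpy() @ self.loadings.to_numpy().T
        return pd.DataFrame(values, index=self.scores.index, columns=self.loadings.index)


def pca(
    matrix: Union[LipidomeMatrix, pd.DataFrame],
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """PCA via singular value decomposition.

    With ``scale`` the correlation rather than covariance structure is
    analysed; a zero-variance variable then triggers a rejection naming it.
    """
    data = _as_frame(matrix)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 samples for PCA")
    if data.isna().any().any():
        raise ValueError("matrix has missing values")
    values = data.to_numpy(dtype=float)
    if center:
        values = values - values.mean(axis=0)
    if scale:
        std = values.std(axis=0, ddof=1)
        if np.any(std == 0):
            constant = data.columns[np.flatnonzero(std == 0)[0]]
            raise ValueError(f"variable {constant!r} has zero variance")
        values = values / std

    u, s, vt = np.linalg.svd(values, full_matrices=False)
    # deterministic orientation: largest-|loading| entry positive
    for j in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[j]))
        if vt[j, pivot] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]

    names = [f"PC{j + 1}" for j in range(len(s))]
    scores = pd.DataFrame(u * s, index=data.index, columns=names)
    loadings = pd.DataFrame(vt.T, index=data.columns, columns=names)
    explained = s**2 / (values.shape[0] - 1)
    return PcaResult(scores=scores, loadings=loadings, explained_variance=explained)


def mean_pairwise_correlation(matrix: Union[LipidomeMatrix, pd.DataFrame]) -> float:
    """Mean pairwise Pearson correlation between the rows of a value grid.

    Used as a clade-tightness summary: with a flat cut of a sample tree,
    the rows of one clade are passed in and their average mutual
    correlation is reported.
    """
    data = _as_frame(matrix).to_numpy(dtype=float)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    corr = np.corrcoef(data)
    upper = corr[np.triu_indices_from(corr, k=1)]
    return float(np.mean(upper))
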