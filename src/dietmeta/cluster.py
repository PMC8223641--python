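"""Hierarchical clustering of foods, species and pathways.

Dendrograms are built over *variables* (foods or microbial features),
using subjects as the dimensions: squared Euclidean distances for foods
and pathways, Bray-Curtis dissimilarity for species. Cutting the tree
at a height yields clusters; each participant then gets a centroid per
cluster — the mean of their values over the cluster's member variables
— which serves as the dietary-pattern exposure or microbial-cluster
response in the association models.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score


class ClusterError(ValueError):
    """Raised for invalid distance matrices or cluster inputs."""


def squared_euclidean(x, y) -> float:
    """Sum of squared coordinate differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ClusterError(f"length mismatch: {x.shape} vs {y.shape}")
    d = x - y
    return float(d @ d)


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ClusterError(f"length mismatch: {x.shape} vs {y.shape}")
    if (x < 0).any() or (y < 0).any():
        raise ClusterError("Bray-Curtis requires non-negative abundances")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ClusterError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.sum(np.abs(x - y)) / denom)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities between variables."""

    values: pd.DataFrame
    metric: str

    def __post_init__(self):
        arr = self.values.to_numpy()
        if arr.shape[0] != arr.shape[1]:
            raise ClusterError("distance matrix must be square")
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ClusterError("distance matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
            raise ClusterError("distance matrix must have a zero diagonal")
        if (arr < -1e-12).any():
            raise ClusterError("distances must be non-negative")

    @property
    def labels(self) -> list:
        return list(self.values.columns)

    def condensed(self) -> np.ndarray:
        return squareform(self.values.to_numpy(), checks=False)


def variable_distances(data: pd.DataFrame, metric: str,
                       standardize: bool = False) -> DistanceMatrix:
    """Pairwise distances between the columns (variables) of ``data``.

    metric: 'sqeuclidean' or 'braycurtis'. Subjects are the dimensions,
    so two foods are close when they are eaten in similar amounts by the
    same people, and two species when they co-occur at similar
    abundances.

    With ``standardize=True`` each variable is z-scored first, so
    squared Euclidean distance becomes 2(n-1)(1 - r) in the Pearson
    correlation r — co-consumption structure rather than intake scale
    then drives the tree. Not defined for Bray-Curtis (which needs
    non-negative values).
    """
    arr = data.to_numpy(dtype=float).T
    if standardize:
        if metric == "braycurtis":
            raise ClusterError("standardization undefined for Bray-Curtis")
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        if (sd <= 0).any():
            raise ClusterError("constant variable; cannot standardize")
        arr = (arr - arr.mean(axis=1, keepdims=True)) / sd
    if metric == "sqeuclidean":
        cond = pdist(arr, metric="sqeuclidean")
    elif metric == "braycurtis":
        if (arr < 0).any():
            raise ClusterError("Bray-Curtis requires non-negative abundances")
        if (arr.sum(axis=1) == 0).any():
            raise ClusterError("all-zero variable; Bray-Curtis undefined")
        cond = pdist(arr, metric="braycurtis")
    else:
        raise ClusterError(f"unknown metric {metric!r}")
    square = pd.DataFrame(squareform(cond), index=data.columns,
                          columns=data.columns)
    return DistanceMatrix(values=square, metric=metric)


@dataclass
class ClusterModel:
    """Dendrogram plus (optionally) a cut and per-participant centroids."""

    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge table
    labels: list
    linkage: str
    metric: str
    cut_height: float | None = None
    memberships: pd.Series | None = None
    centroids: pd.DataFrame | None = None

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    @property
    def n_clusters(self) -> int | None:
        return None if self.memberships is None else self.memberships.nunique()


def hierarchical_cluster(dist: DistanceMatrix,
                         linkage: str = "complete") -> ClusterModel:
    """Agglomerative clustering of a precomputed distance matrix.

    Lance-Williams updates for complete, average or Ward linkage (Ward
    assumes the distances are Euclidean-like). Merging is deterministic
    for a given input ordering.
    """
    if linkage not in ("complete", "average", "ward"):
        raise ClusterError(f"unsupported linkage {linkage!r}")
    n = len(dist.labels)
    if n < 2:
        raise ClusterError("need at least 2 variables to cluster")
    z = hierarchy.linkage(dist.condensed(), method=linkage)
    return ClusterModel(linkage_matrix=z, labels=dist.labels,
                        linkage=linkage, metric=dist.metric)


def cut_dendrogram(model: ClusterModel, height: float) -> pd.Series:
    """Cut the tree, keeping merges at or below ``height``.

    Cluster ids are renumbered 1..k in order of each cluster's first
    member index, so the labelling is deterministic.
    """
    if height < 0:
        raise ClusterError("cut height must be non-negative")
    flat = hierarchy.fcluster(model.linkage_matrix, t=height,
                              criterion="distance")
    memberships = pd.Series(flat, index=model.labels, name="cluster")
    return _renumber(memberships)


def _renumber(memberships: pd.Series) -> pd.Series:
    order = {}
    for label in memberships:
        if label not in order:
            order[label] = len(order) + 1
    return memberships.map(order)


def cut_model(model: ClusterModel, height: float,
              data: pd.DataFrame | None = None) -> ClusterModel:
    """Return a copy of the model with memberships (and centroids) set."""
    memberships = cut_dendrogram(model, height)
    centroids = None
    if data is not None:
        centroids = compute_centroids(data, memberships)
    return replace(model, cut_height=height, memberships=memberships,
                   centroids=centroids)


def compute_centroids(data: pd.DataFrame,
                      memberships: pd.Series) -> pd.DataFrame:
    """Per-participant mean over each cluster's member variables.

    NaN cells (e.g. outlier-masked abundances) are excluded from the
    mean; a participant with every member missing gets a missing
    centroid.
    """
    missing = [v for v in memberships.index if v not in data.columns]
    if missing:
        raise ClusterError(f"memberships refer to unknown variables: {missing}")
    cols = {}
    for cid, members in memberships.groupby(memberships).groups.items():
        cols[f"cluster_{cid}"] = data[list(members)].mean(axis=1)
    return pd.DataFrame(cols, index=data.index)


def clustering_agreement(memberships_a: pd.Series,
                         memberships_b: pd.Series) -> float:
    """Adjusted Rand index between two partitions of the same variables."""
    if set(memberships_a.index) != set(memberships_b.index):
        raise ClusterError("partitions cover different variable sets")
    b = memberships_b.loc[memberships_a.index]
    return float(adjusted_rand_score(memberships_a.to_numpy(), b.to_numpy()))


def best_cut_agreement(model: ClusterModel,
                       reference: pd.Series) -> tuple[float, float]:
    """Max ARI against a reference partition over all merge-height cuts.

    Returns (best ARI, the cut height achieving it). Used to check that
    a planted block structure is recoverable at *some* cut.
    """
    heights = np.unique(model.merge_heights)
    candidates = np.concatenate([[0.0], (heights[:-1] + heights[1:]) / 2.0,
                                 [heights[-1] + 1.0]]) if len(heights) else [0.0]
    best, best_h = -1.0, 0.0
    for h in candidates:
        ari = clustering_agreement(cut_dendrogram(model, h), reference)
        if ari > best:
            best, best_h = ari, float(h)
    return best, best_h


def to_newick(model: ClusterModel) -> str:
    """Export the dendrogram as a Newick string.

    Branch lengths are differences of merge heights, so the root-to-leaf
    path length of a leaf equals the root merge height.
    """
    tree = hierarchy.to_tree(model.linkage_matrix)

    def walk(node, parent_height):
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            name = str(model.labels[node.id]).replace(" ", "_")
            return f"{name}:{parent_height:.10g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    inner = f"({walk(tree.left, tree.dist)},{walk(tree.right, tree.dist)})"
    return inner + ";"
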