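"""Severity-continuum pseudotime on bulk samples.

A deliberately simple trajectory: PCA to ``num_dim`` components on the
variance-stabilized matrix, a 2-D embedding (first two PCs by default, UMAP
optionally), k-means clustering, a minimum spanning tree over the cluster
centroids, rooting at the cluster richest in healthy controls, and
pseudotime as the geodesic tree distance from the root centroid to each
sample's projection onto its nearest tree edge.  The acceptance surface is
recovery of a planted one-dimensional severity continuum, not equality
with any particular published trajectory tool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree, shortest_path
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .io import ExpressionMatrix
from .stats import bh_adjust, rank_sum_test_matrix

__all__ = ["TrajectoryResult", "embed", "cluster_samples", "pseudotime", "top_markers",
           "MARKER_Q_THRESHOLD", "SPECIFICITY_THRESHOLD"]

MARKER_Q_THRESHOLD = 0.01
SPECIFICITY_THRESHOLD = 0.50


@dataclass
class TrajectoryResult:
    """Embedding, clustering, centroid tree and per-sample pseudotime."""

    embedding: pd.DataFrame  # samples x 2
    pca_scores: pd.DataFrame | None
    cluster: pd.Series  # labels contiguous from 1
    mst_edges: list[tuple[int, int, float]]
    root_cluster: int
    pseudotime: pd.Series  # nonneg, min attained inside the root cluster

    def as_frame(self) -> pd.DataFrame:
        df = self.embedding.copy()
        df.columns = ["x", "y"]
        df["cluster"] = self.cluster
        df["pseudotime"] = self.pseudotime
        return df


def embed(
    expr: ExpressionMatrix,
    num_dim: int = 50,
    seed: int = 0,
    backend: str = "pca",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reduce samples to ``num_dim`` PCs and a 2-D embedding.

    Log2 input is anti-logged and re-stabilized with log1p before centering,
    so very bright genes do not dominate the components.  ``backend="pca"``
    uses the first two components for the 2-D view; ``backend="umap"`` runs
    a seeded UMAP on the PC scores.
    """
    X = expr.values.to_numpy(dtype=float).T  # samples x genes
    if expr.scale_tag == "log2":
        X = np.log1p(np.exp2(X))
    if np.allclose(X.std(axis=0).sum(), 0):
        raise ValueError("constant expression matrix")
    n_samples = X.shape[0]
    if num_dim > n_samples - 1:
        warnings.warn(
            f"num_dim={num_dim} exceeds samples-1; lowered to {n_samples - 1}",
            stacklevel=2,
        )
        num_dim = n_samples - 1
    num_dim = min(num_dim, X.shape[1])
    pca = PCA(n_components=num_dim, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(X - X.mean(axis=0))
    pcs = pd.DataFrame(
        scores, index=expr.sample_ids, columns=[f"PC{i + 1}" for i in range(num_dim)]
    )
    if backend == "pca":
        emb = pcs.iloc[:, :2].to_numpy()
    elif backend == "umap":
        import umap

        emb = umap.UMAP(n_components=2, random_state=seed).fit_transform(scores)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    embedding = pd.DataFrame(emb, index=expr.sample_ids, columns=["dim1", "dim2"])
    return pcs, embedding


def cluster_samples(embedding: pd.DataFrame, k: int = 3, seed: int = 0) -> pd.Series:
    """K-means cluster labels (contiguous from 1) on the 2-D embedding."""
    n = embedding.shape[0]
    if k > n / 3:
        raise ValueError(f"k={k} too large for {n} samples (need >= 3k)")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(embedding.to_numpy(dtype=float))
    return pd.Series(labels + 1, index=embedding.index, name="cluster")


def _project_to_segment(p, a, b):
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    proj = a + t * ab
    return proj, t


def pseudotime(
    embedding: pd.DataFrame,
    labels: pd.Series,
    control_ids: list[str],
    pca_scores: pd.DataFrame | None = None,
) -> TrajectoryResult:
    """Geodesic pseudotime along the centroid minimum spanning tree.

    The root is the cluster with the largest control fraction (ties broken
    toward the larger cluster); each sample projects onto the nearest tree
    edge and its pseudotime is the tree distance from the root centroid to
    that projection.
    """
    ctrl = [s for s in control_ids if s in embedding.index]
    if not ctrl:
        raise ValueError("no control samples provided")
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    pts = embedding.to_numpy(dtype=float)
    centroids = np.stack(
        [pts[(labels == c).to_numpy()].mean(axis=0) for c in clusters]
    )

    dmat = cdist(centroids, centroids)
    mst = minimum_spanning_tree(dmat).toarray()
    mst = np.maximum(mst, mst.T)
    edges = [
        (clusters[i], clusters[j], float(mst[i, j]))
        for i in range(len(clusters))
        for j in range(i + 1, len(clusters))
        if mst[i, j] > 0
    ]

    ctrl_set = set(ctrl)
    frac = []
    for c in clusters:
        members = labels.index[labels == c]
        frac.append(
            (sum(s in ctrl_set for s in members) / len(members), len(members), c)
        )
    root = max(frac)[2]  # control fraction first, then size

    tree_dist = shortest_path(np.where(mst > 0, mst, 0), method="D", directed=False)
    ridx = clusters.index(root)

    times = np.empty(pts.shape[0])
    for si in range(pts.shape[0]):
        p = pts[si]
        best = np.inf
        for (cu, cv, _w) in edges:
            iu, iv = clusters.index(cu), clusters.index(cv)
            proj, _t = _project_to_segment(p, centroids[iu], centroids[iv])
            d_edge = float(np.linalg.norm(p - proj))
            via_u = tree_dist[ridx, iu] + float(np.linalg.norm(proj - centroids[iu]))
            via_v = tree_dist[ridx, iv] + float(np.linalg.norm(proj - centroids[iv]))
            cand = min(via_u, via_v)
            # nearest edge wins; geodesic measured along the tree
            if d_edge < best:
                best = d_edge
                best_time = cand
        times[si] = best_time
    return TrajectoryResult(
        embedding=embedding.copy(),
        pca_scores=pca_scores,
        cluster=labels.copy(),
        mst_edges=edges,
        root_cluster=int(root),
        pseudotime=pd.Series(times, index=embedding.index, name="pseudotime"),
    )


def top_markers(
    expr: ExpressionMatrix,
    labels: pd.Series,
    q_threshold: float = MARKER_Q_THRESHOLD,
    specificity_threshold: float = SPECIFICITY_THRESHOLD,
) -> pd.DataFrame:
    """Cluster-specific marker genes.

    Per gene and cluster: a two-sided rank-sum test of the cluster against
    the rest (BH across genes within the cluster) and a specificity score —
    the cluster's mean linear expression divided by the total of the
    per-cluster means.  Rows passing both gates (q < 0.01 and specificity
    >= 0.50) are retained.
    """
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    usable = []
    for c in clusters:
        n = int((labels == c).sum())
        if n < 3:
            warnings.warn(f"cluster {c} has {n} samples; excluded", stacklevel=2)
        else:
            usable.append(c)
    if len(usable) < 2:
        raise ValueError("fewer than two clusters with >= 3 samples")
    vals = expr.values
    linear = np.exp2(vals.to_numpy(dtype=float)) if expr.scale_tag == "log2" else vals.to_numpy()
    sample_order = list(vals.columns)
    lab = labels.loc[sample_order].to_numpy()

    cluster_means = {
        c: linear[:, lab == c].mean(axis=1) for c in usable
    }
    total = np.sum(list(cluster_means.values()), axis=0)
    records = []
    for c in usable:
        in_c = lab == c
        a = vals.to_numpy(dtype=float)[:, in_c]
        b = vals.to_numpy(dtype=float)[:, ~in_c]
        _, p = rank_sum_test_matrix(a, b)
        q = bh_adjust(np.clip(p, np.finfo(float).tiny, 1.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            spec = np.where(total > 0, cluster_means[c] / total, 0.0)
        keep = (q < q_threshold) & (spec >= specificity_threshold)
        for gi in np.flatnonzero(keep):
            records.append(
                {"gene": vals.index[gi], "cluster": c,
                 "specificity": float(spec[gi]), "marker_q": float(q[gi])}
            )
    return pd.DataFrame(records, columns=["gene", "cluster", "specificity", "marker_q"])
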