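"""Hierarchical partition of the lesion cloud into treatment regions.

The lesion is agglomerated under weighted centre-of-mass (WPGMC / median)
linkage — Lance-Williams coefficients alpha1 = alpha2 = 1/2, beta = -1/4,
gamma = 0 on Euclidean distances of the 3D coordinates — and the tree is
cut at a maximum region count (default 50).  Each region contributes one
centre point, and the optimizer prescribes the target irradiance at those
centres instead of at every point, which keeps the bounded least-squares
problem small.

The merge tree itself comes from scipy's median-linkage implementation;
only positions enter the metric (normals and colors are ignored).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .cloud import PointCloud

__all__ = ["ClusterAssignment", "linkage_wpgmc", "cut_maxclust", "summarize_clusters", "cluster_cloud"]


@dataclass
class ClusterAssignment:
    """Partition of a cloud into K regions with centroid summary points."""

    labels: np.ndarray  # (N,) ids in 1..K
    centers: np.ndarray  # (K, 3) mm
    center_normals: np.ndarray | None  # (K, 3) unit vectors
    sizes: np.ndarray  # (K,) member counts

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def center_cloud(self, frame: str = "array") -> PointCloud:
        return PointCloud(self.centers, self.center_normals, frame=frame)


def linkage_wpgmc(points: np.ndarray) -> np.ndarray:
    """WPGMC (median-linkage) merge tree of 3D points.

    Returns the standard (N-1, 4) linkage matrix: merged ids, merge height
    (Euclidean distance between the merged clusters' weighted centres) and
    member count.  A single point yields an empty tree.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] < 1:
        raise ValueError("need at least one point")
    if points.shape[0] == 1:
        return np.empty((0, 4))
    return linkage(points, method="median")


def cut_maxclust(tree: np.ndarray, n_max: int, n_obs: int | None = None) -> np.ndarray:
    """Cut the merge tree at the smallest height giving at most n_max clusters.

    Labels are renumbered 1..K in order of first occurrence.
    """
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    if tree.shape[0] == 0:
        return np.ones(n_obs or 1, dtype=int)
    raw = fcluster(tree, t=n_max, criterion="maxclust")
    return _renumber(raw)


def _renumber(labels: np.ndarray) -> np.ndarray:
    order = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order) + 1
        out[i] = order[lab]
    return out


def summarize_clusters(cloud: PointCloud, labels: np.ndarray) -> ClusterAssignment:
    """Centroids, mean normals and sizes of every labelled region."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (len(cloud),):
        raise ValueError("labels must assign one region per point")
    ks = np.unique(labels)
    if ks.min() < 1:
        raise ValueError("labels must be 1-based region ids")
    k = ks.max()
    centers = np.empty((k, 3))
    sizes = np.empty(k, dtype=int)
    normals = None if cloud.normals is None else np.empty((k, 3))
    for i in range(1, k + 1):
        members = labels == i
        if not members.any():
            raise ValueError(f"cluster {i} has no members")
        centers[i - 1] = cloud.positions[members].mean(axis=0)
        sizes[i - 1] = members.sum()
        if normals is not None:
            mean = cloud.normals[members].mean(axis=0)
            norm = np.linalg.norm(mean)
            if norm < 1e-12:
                raise ValueError(f"cluster {i} has antipodal normals (degenerate mean)")
            normals[i - 1] = mean / norm
    return ClusterAssignment(labels, centers, normals, sizes)


def cluster_cloud(
    cloud: PointCloud,
    max_clusters: int = 50,
    height_threshold: float | None = None,
    max_tree_points: int = 6000,
    seed: int = 0,
) -> ClusterAssignment:
    """End-to-end partition of a cloud into at most ``max_clusters`` regions.

    The merge tree needs the full pairwise-distance matrix, so clouds larger
    than ``max_tree_points`` are clustered on a seeded uniform subsample and
    the remaining points are assigned to the nearest subsample centroid; the
    returned centres are recomputed from the full membership.  An optional
    ``height_threshold`` additionally cuts the tree at that merge height
    (whichever cut yields fewer clusters wins).
    """
    pts = cloud.positions
    if len(cloud) > max_tree_points:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(cloud), max_tree_points, replace=False))
        tree = linkage_wpgmc(pts[idx])
        sub_labels = cut_maxclust(tree, max_clusters, n_obs=len(idx))
        if height_threshold is not None:
            alt = _renumber(fcluster(tree, t=height_threshold, criterion="distance"))
            if alt.max() < sub_labels.max():
                sub_labels = alt
        k = sub_labels.max()
        cen = np.stack([pts[idx][sub_labels == i].mean(axis=0) for i in range(1, k + 1)])
        d2 = ((pts[:, None, :] - cen[None, :, :]) ** 2).sum(axis=2)
        labels = _renumber(d2.argmin(axis=1) + 1)
    else:
        tree = linkage_wpgmc(pts)
        labels = cut_maxclust(tree, max_clusters, n_obs=len(cloud))
        if height_threshold is not None and tree.shape[0] > 0:
            alt = _renumber(fcluster(tree, t=height_threshold, criterion="distance"))
            if alt.max() < labels.max():
                labels = alt
    return summarize_clusters(cloud, labels)
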