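"""Density clustering of mutant-cell coordinates and clone-expansion statistics.

Mutant-cell foci in segmented tissue images are identified by DBSCAN on
the cell centroids (Euclidean distance, neighbourhood radius ``eps``; the
study used ``eps = 35`` image units).  With ``min_pts = 1`` every point is
a core point and the clusters are exactly the connected components of the
eps-neighbourhood graph, so isolated single cells count as singleton foci
— the convention required for an average focus size of ~2 cells shortly
after oncogene induction to be representable.  A focus is called an
"expanded clone" when it holds strictly more than ``threshold`` cells
(study: >5 at 10 weeks, based on at most one division of wild-type
alveolar cells between 3 and 10 weeks).

Coordinates and ``eps`` share the input table's units (pixels in the
study); unit conversion is the caller's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

__all__ = [
    "ClusterSet",
    "density_cluster",
    "average_cluster_size",
    "expanded_fraction",
]


@dataclass(frozen=True)
class ClusterSet:
    """Cluster assignment of a point set.

    ``labels[i]`` is the cluster id of point ``i`` (-1 marks noise, which
    only occurs for ``min_pts > 1``).  ``sizes`` counts the cells per
    cluster, ordered by cluster id.
    """

    labels: np.ndarray
    eps: float
    min_pts: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=int))

    @property
    def n_clusters(self) -> int:
        return int(np.max(self.labels, initial=-1) + 1)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels[self.labels >= 0], minlength=self.n_clusters)

    @property
    def n_noise(self) -> int:
        return int(np.sum(self.labels == -1))


def _as_points(points) -> np.ndarray:
    if hasattr(points, "loc") and {"x", "y"} <= set(points.columns):
        points = points[["x", "y"]].to_numpy()
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1 and pts.size == 2:
        pts = pts.reshape(1, 2)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValueError("points must be a non-empty (n, 2) array of coordinates")
    if not np.all(np.isfinite(pts)):
        raise ValueError("coordinates must be finite")
    return pts


def density_cluster(points, eps: float = 35.0, min_pts: int = 1) -> ClusterSet:
    """DBSCAN-cluster cell coordinates.

    Parameters
    ----------
    points : array-like of shape (n, 2) or DataFrame with ``x``/``y``
        Cell centroid coordinates, in the same units as ``eps``.
    eps : float
        Neighbourhood radius; boundary inclusive (d <= eps).
    min_pts : int
        Core-point density threshold (sklearn's ``min_samples``, counting
        the point itself).  Default 1: singleton foci are clusters.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    pts = _as_points(points)
    labels = DBSCAN(eps=eps, min_samples=min_pts).fit(pts).labels_
    return ClusterSet(labels=labels, eps=eps, min_pts=min_pts)


def average_cluster_size(clusters: ClusterSet) -> float:
    """Mean number of cells per cluster (noise points excluded)."""
    if clusters.n_clusters == 0:
        raise ValueError("no clusters present")
    return float(np.mean(clusters.sizes))


def expanded_fraction(clusters: ClusterSet, threshold: int = 5) -> float:
    """Fraction of clusters with strictly more than ``threshold`` cells."""
    if clusters.n_clusters == 0:
        raise ValueError("no clusters present")
    return float(np.mean(clusters.sizes > threshold))
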