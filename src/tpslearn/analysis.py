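"""Post-hoc mechanism analysis of a transition path ensemble.

Sampled paths are projected onto a low-dimensional coordinate plane (e.g.
the two contacts selected by symbolic regression), pairwise similarities are
computed by dynamic time warping — which handles the unequal path lengths —
and agglomerative clustering of the distance matrix separates competing
reaction channels.  Per-cluster density maps count, for every grid cell, the
number of *paths* that visit it (a path visiting a cell many times still
contributes one), which highlights where routes go rather than where they
linger.

DTW as computed here satisfies identity and symmetry but not the triangle
inequality; it is a dissimilarity, not a metric, which average-linkage
clustering tolerates.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .sampling import Path

__all__ = [
    "dtw_distance",
    "hierarchical_cluster",
    "pairwise_dtw",
    "path_density",
    "project_paths",
    "resample_polyline",
]


def project_paths(
    paths: Sequence[Path] | Sequence[np.ndarray],
    coords: tuple[Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]] | tuple[int, int],
) -> list[np.ndarray]:
    """One 2D polyline per path, frame order preserved.

    ``coords`` is either a pair of column indices or a pair of per-frame
    coordinate functions mapping an (n, d) frame array to an (n,) vector.
    """
    out = []
    for p in paths:
        frames = p.positions if isinstance(p, Path) else np.atleast_2d(np.asarray(p, float))
        if isinstance(coords[0], int):
            i, j = coords
            if max(i, j) >= frames.shape[1]:
                raise ValueError("coordinate index out of range")
            poly = frames[:, [i, j]]
        else:
            fx, fy = coords
            poly = np.column_stack([np.asarray(fx(frames), float),
                                    np.asarray(fy(frames), float)])
        out.append(poly.astype(float))
    return out


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Classic dynamic-time-warping distance with Euclidean local cost.

    D[i,j] = cost(i,j) + min(D[i-1,j], D[i,j-1], D[i-1,j-1]); returns
    D[n-1,m-1].  Symmetric, zero iff the sequences are identical.
    """
    a = np.atleast_2d(np.asarray(a, float))
    b = np.atleast_2d(np.asarray(b, float))
    if a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("polylines must be nonempty")
    n, m = a.shape[0], b.shape[0]
    # local cost matrix, then DP row by row
    diff = a[:, None, :] - b[None, :, :]
    cost = np.sqrt(np.sum(diff * diff, axis=2))
    prev = np.empty(m)
    prev[0] = cost[0, 0]
    for j in range(1, m):
        prev[j] = prev[j - 1] + cost[0, j]
    cur = np.empty(m)
    for i in range(1, n):
        cur[0] = prev[0] + cost[i, 0]
        ci = cost[i]
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = ci[j] + best
        prev, cur = cur, prev
    return float(prev[m - 1])


def resample_polyline(poly: np.ndarray, n_points: int) -> np.ndarray:
    """Arc-length resampling to a fixed number of points."""
    poly = np.atleast_2d(np.asarray(poly, float))
    if poly.shape[0] == 1:
        return np.repeat(poly, n_points, axis=0)
    seg = np.sqrt(np.sum(np.diff(poly, axis=0) ** 2, axis=1))
    t = np.concatenate([[0.0], np.cumsum(seg)])
    if t[-1] == 0:
        return np.repeat(poly[:1], n_points, axis=0)
    ti = np.linspace(0.0, t[-1], n_points)
    return np.column_stack([np.interp(ti, t, poly[:, k]) for k in range(poly.shape[1])])


def pairwise_dtw(polylines: Sequence[np.ndarray], resample: int | None = 64) -> np.ndarray:
    """Symmetric DTW distance matrix over an ensemble of polylines.

    ``resample`` arc-length-resamples each polyline first (None keeps the raw
    frames); this bounds the quadratic DP cost for long paths while leaving
    the path geometry intact.
    """
    polys = [resample_polyline(p, resample) if resample else np.atleast_2d(np.asarray(p, float))
             for p in polylines]
    n = len(polys)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(polys[i], polys[j])
    return D


def hierarchical_cluster(distance_matrix: np.ndarray, n_clusters: int,
                         method: str = "average") -> tuple[np.ndarray, np.ndarray]:
    """Agglomerative clustering of a precomputed distance matrix.

    Returns (labels in 1..n_clusters, scipy linkage matrix).  Average
    linkage by default; the linkage matrix serializes the full dendrogram.
    """
    D = np.asarray(distance_matrix, float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    Z = linkage(squareform(D, checks=False), method=method)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    return labels, Z


def path_density(polylines: Sequence[np.ndarray], x_edges: np.ndarray,
                 y_edges: np.ndarray) -> np.ndarray:
    """Per-path visitation histogram on a 2D grid.

    Each path increments a cell's counter at most once no matter how many
    frames fall inside it, so no cell exceeds the number of paths.
    """
    x_edges = np.asarray(x_edges, float)
    y_edges = np.asarray(y_edges, float)
    H = np.zeros((len(x_edges) - 1, len(y_edges) - 1))
    for poly in polylines:
        poly = np.atleast_2d(np.asarray(poly, float))
        h, _, _ = np.histogram2d(poly[:, 0], poly[:, 1], bins=[x_edges, y_edges])
        H += h > 0
    return H
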