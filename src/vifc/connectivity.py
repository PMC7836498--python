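"""Seed-based functional connectivity and the connectivity-distance statistic.

A significant cluster from the brain-behavior maps ("sigCluster") serves
as a seed region: its mean time series is correlated with every other
cortical vertex, the resulting p-map is Bonferroni-thresholded, and the
connectivity distance of a subject is the average anatomical distance
between the cluster and the surviving vertices. Per-subject distances are
averaged over all clusters belonging to one behavior/configuration and
compared between groups with a two-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from scipy.sparse.csgraph import dijkstra

from .glm import SigCluster
from .surface_io import SurfaceMesh, VertexTimeSeries

__all__ = [
    "ConnectivityDistanceResult",
    "seed_timeseries",
    "seed_fc_map",
    "bonferroni_mask",
    "cluster_vertex_distances",
    "compute_connectivity_distance",
    "aggregate_behavior_distance",
    "compare_groups",
]


@dataclass
class ConnectivityDistanceResult:
    """Connectivity distance of one subject for one seed cluster."""

    subject_id: str
    cluster_id: str
    n_significant_vertices: int
    distance_mm: float  # NaN when no significant vertices survive
    metric: str = "geodesic"
    alpha_bonferroni: float = 0.05

    @property
    def defined(self) -> bool:
        return self.n_significant_vertices > 0 and np.isfinite(self.distance_mm)


def seed_timeseries(ts: VertexTimeSeries, cluster: SigCluster | np.ndarray) -> np.ndarray:
    """Timepoint-wise mean BOLD series over the cluster vertices."""
    ids = cluster.vertex_ids if isinstance(cluster, SigCluster) else np.asarray(cluster)
    if len(ids) == 0:
        raise ValueError("empty seed cluster")
    if not ts.mesh.cortex_mask[ids].all():
        raise ValueError("seed cluster contains masked vertices")
    return ts.values[ids].mean(axis=0)


def seed_fc_map(
    ts: VertexTimeSeries, cluster: SigCluster | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Whole-surface functional connectivity of the seed cluster.

    Returns per-vertex ``(r, p)``: Pearson correlation of the seed mean
    series with every unmasked non-cluster vertex, and the two-sided p
    from ``t = r * sqrt((N - 2) / (1 - r^2))`` on N - 2 degrees of
    freedom. Cluster members, masked vertices and zero-variance vertices
    are NaN.
    """
    ids = cluster.vertex_ids if isinstance(cluster, SigCluster) else np.asarray(cluster)
    seed = seed_timeseries(ts, ids)
    if np.ptp(seed) == 0:
        raise ValueError("seed series is constant")
    x = ts.values
    n_t = ts.n_timepoints
    seed_c = seed - seed.mean()
    cx = x - x.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", cx, cx))
    seed_norm = float(np.linalg.norm(seed_c))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (cx @ seed_c) / (norms * seed_norm)
    r[norms == 0] = np.nan
    r[~ts.mesh.cortex_mask] = np.nan
    r[ids] = np.nan
    np.clip(r, -1.0, 1.0, out=r)
    dof = n_t - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt(dof / (1.0 - r * r))
    p = np.where(np.isfinite(r), 2.0 * stats.t.sf(np.abs(t), dof), np.nan)
    p[np.isfinite(r) & (np.abs(r) >= 1.0)] = 0.0
    return r, p


def bonferroni_mask(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Significant iff ``p < alpha / m`` with m = number of finite tests."""
    p = np.asarray(pvals, dtype=np.float64)
    m = int(np.isfinite(p).sum())
    if m == 0:
        raise ValueError("no tested p-values")
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(p), p < alpha / m, False)


def cluster_vertex_distances(
    cluster_ids: np.ndarray,
    mesh: SurfaceMesh,
    metric: str = "geodesic",
) -> np.ndarray:
    """Distance from the cluster to every vertex, per cluster member.

    Returns an (n_cluster, V) array of d(c, v). Geodesic distances run
    Dijkstra from every cluster vertex over the unmasked edge graph;
    Euclidean distances are straight-line.
    """
    cluster_ids = np.asarray(cluster_ids, dtype=np.int64)
    if metric == "geodesic":
        from .mesh_geometry import _mask_adjacency, geodesic_graph

        adj = _mask_adjacency(geodesic_graph(mesh), mesh.cortex_mask)
        return dijkstra(adj, directed=False, indices=cluster_ids)
    if metric == "euclidean":
        diff = mesh.vertex_coords[None, :, :] - mesh.vertex_coords[cluster_ids][:, None, :]
        return np.linalg.norm(diff, axis=2)
    raise ValueError(f"unknown metric {metric!r}")


def compute_connectivity_distance(
    cluster: SigCluster | np.ndarray,
    sig_vertices: np.ndarray,
    mesh: SurfaceMesh,
    metric: str = "geodesic",
    aggregation: str = "mean",
    *,
    distances: np.ndarray | None = None,
) -> float:
    """Average distance between a cluster and its significant FC vertices.

    For each significant vertex ``v`` the cluster-to-vertex distance is,
    per ``aggregation``: ``"mean"`` (default) the mean of d(c, v) over
    cluster members, ``"min"`` the minimum, or ``"centroid"`` (Euclidean
    only) the distance from the cluster centroid. The statistic is the
    mean over significant vertices, in mm; NaN (undefined, never zero)
    when ``sig_vertices`` is empty. Cluster members must already be
    excluded from ``sig_vertices``.

    ``distances`` may pass a precomputed (n_cluster, V) matrix from
    :func:`cluster_vertex_distances` to amortize Dijkstra across subjects.
    """
    ids = cluster.vertex_ids if isinstance(cluster, SigCluster) else np.asarray(cluster)
    sig = np.asarray(sig_vertices, dtype=np.int64)
    if np.intersect1d(ids, sig).size:
        raise ValueError("sig_vertices must exclude cluster members")
    if sig.size == 0:
        return float("nan")
    if aggregation == "centroid":
        if metric != "euclidean":
            raise ValueError("centroid aggregation requires the euclidean metric")
        centroid = mesh.vertex_coords[ids].mean(axis=0)
        return float(
            np.linalg.norm(mesh.vertex_coords[sig] - centroid, axis=1).mean()
        )
    if distances is None:
        distances = cluster_vertex_distances(ids, mesh, metric)
    d = distances[:, sig]
    if aggregation == "mean":
        per_vertex = d.mean(axis=0)
    elif aggregation == "min":
        per_vertex = d.min(axis=0)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return float(per_vertex.mean())


def aggregate_behavior_distance(
    results: Sequence[ConnectivityDistanceResult],
) -> Mapping[str, float]:
    """Per-subject mean connectivity distance across clusters.

    Averages each subject's finite cluster distances; a subject with no
    finite result maps to NaN (flagged missing).
    """
    by_subject: dict[str, list[float]] = {}
    for res in results:
        by_subject.setdefault(res.subject_id, [])
        if res.defined:
            by_subject[res.subject_id].append(res.distance_mm)
    return {
        sid: (float(np.mean(vals)) if vals else float("nan"))
        for sid, vals in by_subject.items()
    }


def compare_groups(
    distances_a: np.ndarray,
    distances_b: np.ndarray,
    *,
    equal_var: bool = True,
) -> tuple[float, float]:
    """Two-sample t-test of per-subject connectivity distances.

    Returns ``(t, p)``; equal-variance (Student) by default, Welch when
    ``equal_var=False``. NaN entries (subjects without significant FC)
    are dropped.
    """
    a = np.asarray(distances_a, dtype=np.float64)
    b = np.asarray(distances_b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 finite distances")
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
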