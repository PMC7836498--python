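"""Independent brute-force reference implementations used only by tests.

Each function is a direct, unoptimized translation of the definition it
checks (explicit loops, textbook formulas) and deliberately avoids the
code paths of the package under test.
"""

from __future__ import annotations

import heapq
import math

import numpy as np


def mesh_edges(faces: np.ndarray) -> set[tuple[int, int]]:
    edges: set[tuple[int, int]] = set()
    for a, b, c in faces:
        for u, v in ((a, b), (b, c), (a, c)):
            edges.add((min(int(u), int(v)), max(int(u), int(v))))
    return edges


def geodesic_pairs(faces: np.ndarray) -> set[tuple[int, int]]:
    """Mesh edges plus the opposite-vertex shortcut of adjacent triangles."""
    pairs = mesh_edges(faces)
    by_edge: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for u, v in ((f[0], f[1]), (f[1], f[2]), (f[0], f[2])):
            by_edge.setdefault((min(int(u), int(v)), max(int(u), int(v))), []).append(fi)
    for (u, v), fl in by_edge.items():
        if len(fl) == 2:
            opp = [int(w) for fi in fl for w in faces[fi] if w != u and w != v]
            if opp[0] != opp[1]:
                pairs.add((min(opp), max(opp)))
    return pairs


def dijkstra_brute(
    coords: np.ndarray, faces: np.ndarray, source: int, mask: np.ndarray | None = None
) -> np.ndarray:
    """Textbook heap Dijkstra over the augmented mesh edge graph."""
    n = len(coords)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for u, v in geodesic_pairs(faces):
        if mask[u] and mask[v]:
            w = float(math.dist(coords[u], coords[v]))
            adj[u].append((v, w))
            adj[v].append((u, w))
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def pearson_pair(x, y) -> float:
    """Pearson r from the raw definitional sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y))
    if den == 0:
        return float("nan")
    return num / den


def std_raw(x) -> float:
    """Root sum of squared deviations (the criticality STD term)."""
    n = len(x)
    m = sum(x) / n
    return math.sqrt(sum((a - m) ** 2 for a in x))


def vifc_brute(
    values: np.ndarray,
    coords: np.ndarray,
    faces: np.ndarray,
    distance_threshold: float,
    connectivity_threshold: float,
    mask: np.ndarray | None = None,
    metric: str = "geodesic",
) -> np.ndarray:
    """Loop-and-formula evaluation of the criticality index at every vertex."""
    n = len(values)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    out = np.full(n, np.nan)
    for i in range(n):
        if not mask[i]:
            continue
        if std_raw(values[i]) == 0:
            continue
        if metric == "geodesic":
            dist = dijkstra_brute(coords, faces, i, mask)
        else:
            dist = np.array([math.dist(coords[i], coords[j]) for j in range(n)])
        in_r, out_r = [], []
        for j in range(n):
            if j == i or not mask[j]:
                continue
            if std_raw(values[j]) == 0:
                continue
            r = pearson_pair(values[i], values[j])
            if r < connectivity_threshold:
                continue
            if dist[j] < distance_threshold:
                in_r.append(r)
            else:
                out_r.append(r)
        if in_r and out_r:
            out[i] = (
                std_raw(values[i])
                * (sum(in_r) / len(in_r))
                / (sum(out_r) / len(out_r))
            )
    return out


def nvifc_brute(
    values: np.ndarray,
    faces: np.ndarray,
    connectivity_threshold: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """One-ring variant of the brute-force criticality index."""
    n = len(values)
    if mask is None:
        mask = np.ones(n, dtype=bool)
    ring: list[set[int]] = [set() for _ in range(n)]
    for u, v in mesh_edges(faces):
        ring[u].add(v)
        ring[v].add(u)
    out = np.full(n, np.nan)
    for i in range(n):
        if not mask[i] or std_raw(values[i]) == 0:
            continue
        in_r, out_r = [], []
        for j in range(n):
            if j == i or not mask[j] or std_raw(values[j]) == 0:
                continue
            r = pearson_pair(values[i], values[j])
            if r < connectivity_threshold:
                continue
            (in_r if j in ring[i] else out_r).append(r)
        if in_r and out_r:
            out[i] = (
                std_raw(values[i])
                * (sum(in_r) / len(in_r))
                / (sum(out_r) / len(out_r))
            )
    return out


def bh_stepup(pvals, alpha: float) -> np.ndarray:
    """Definitional Benjamini-Hochberg: largest k with p_(k) <= alpha*k/m."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha * k / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


def connected_components_brute(
    vertices: set[int], faces: np.ndarray
) -> list[set[int]]:
    """BFS connected components of a vertex subset on the mesh edge graph."""
    adj: dict[int, set[int]] = {v: set() for v in vertices}
    for u, v in mesh_edges(faces):
        if u in vertices and v in vertices:
            adj[u].add(v)
            adj[v].add(u)
    seen: set[int] = set()
    comps = []
    for v in sorted(vertices):
        if v in seen:
            continue
        comp = {v}
        queue = [v]
        while queue:
            u = queue.pop()
            for w in adj[u]:
                if w not in comp:
                    comp.add(w)
                    queue.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def connectivity_distance_brute(
    cluster_ids, sig_ids, dist_fn, aggregation: str = "mean"
) -> float:
    """Double loop over (cluster member, significant vertex) pairs."""
    if len(sig_ids) == 0:
        return float("nan")
    per_vertex = []
    for v in sig_ids:
        ds = [dist_fn(c, v) for c in cluster_ids]
        per_vertex.append(sum(ds) / len(ds) if aggregation == "mean" else min(ds))
    return sum(per_vertex) / len(per_vertex)


def ttest_formula(a, b) -> tuple[float, float]:
    """Equal-variance two-sample t from the textbook pooled formula."""
    from scipy import stats as sps

    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * sps.t.sf(abs(t), na + nb - 2)
    return t, p


def partial_corr_matrix_identity(x, y, Z) -> float:
    """Partial correlation from the inverse of the full correlation matrix."""
    data = np.column_stack([x, y, Z])
    corr = np.corrcoef(data, rowvar=False)
    omega = np.linalg.inv(corr)
    return -omega[0, 1] / math.sqrt(omega[0, 0] * omega[1, 1])
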