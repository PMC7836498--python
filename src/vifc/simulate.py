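"""Synthetic meshes, BOLD-like signals, and cohorts with planted effects.

The generators provide everything needed to exercise the full analysis
chain without any imaging data: closed icosphere meshes standing in for a
cortical hemisphere (default radius 75 mm, so the 14-56 mm distance-
threshold grid spans locally-to-broadly, echoing the scale of the
fsaverage5 surface), a Gaussian latent-factor signal model

    x_i(t) = sum_c a_c * f_c(t) * [i in cluster c] + b * g(t) + sigma * eps_i(t)

with independent standard-normal factors (so inter-vertex correlations
and temporal variances have closed forms — two vertices sharing one
cluster factor with weight ``a`` on noise ``sigma`` correlate at
``a^2 / (a^2 + sigma^2)``), and cohort generators that tie a subject's
cluster coherence ``a`` linearly to a behavioral score to plant
brain-behavior associations for parameter-recovery experiments.

Everything is a pure function of its parameters and an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import trimesh

from .mesh_geometry import geodesic_graph
from .surface_io import BehaviorTable, SurfaceMesh, VertexTimeSeries

import pandas as pd
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "ClusterSpec",
    "SignalModel",
    "CohortSpec",
    "make_icosphere",
    "make_chain_mesh",
    "cluster_members",
    "simulate_bold",
    "simulate_cohort",
]

MAX_SUBDIVISIONS = 6  # fixture scale guard


@dataclass(frozen=True)
class ClusterSpec:
    """A planted coherent patch: geodesic ball around a center vertex.

    ``factor`` < 0 gives the patch its own latent series; patches that
    declare the same non-negative ``factor`` id share one latent series,
    which plants long-range functional connectivity between them.
    """

    center: int
    radius_mm: float
    weight: float  # coherence weight a >= 0
    factor: int = -1

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("cluster radius must be > 0")
        if self.weight < 0:
            raise ValueError("cluster weight must be >= 0")


@dataclass(frozen=True)
class SignalModel:
    """Latent-factor BOLD model: planted clusters + global signal + noise."""

    cluster_specs: tuple[ClusterSpec, ...] = ()
    global_weight: float = 0.0
    noise_sd: float = 1.0
    n_timepoints: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.global_weight < 0 or self.noise_sd < 0:
            raise ValueError("weights must be >= 0")
        if (
            self.global_weight == 0
            and self.noise_sd == 0
            and all(c.weight == 0 for c in self.cluster_specs)
        ):
            raise ValueError("at least one of a, b, sigma must be > 0")
        if self.n_timepoints < 3:
            raise ValueError("need >= 3 timepoints")


def make_icosphere(subdivisions: int, radius_mm: float = 75.0) -> SurfaceMesh:
    """Closed triangulated sphere with ``10 * 4**s + 2`` vertices.

    Subdivision 2 (162 vertices) is the workhorse fixture; subdivision 4
    (2562 vertices) approaches a downsampled hemisphere. ``subdivisions``
    above 6 is refused as a fixture scale guard.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if subdivisions > MAX_SUBDIVISIONS:
        raise ValueError(f"subdivisions > {MAX_SUBDIVISIONS} refused (fixture guard)")
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius_mm)
    return SurfaceMesh(
        np.asarray(tm.vertices, dtype=np.float64),
        np.asarray(tm.faces, dtype=np.int64),
        hemisphere="synthetic",
    )


def make_chain_mesh(n_vertices: int, spacing_mm: float = 4.0) -> SurfaceMesh:
    """Collinear chain of vertices joined by degenerate-thin triangles.

    Handy for hand-checkable distance tests: vertex ``i`` sits at
    ``(i * spacing, 0, z_i)`` with a tiny alternating z offset so faces
    are non-degenerate; the edge graph contains the path 0-1-...-n-1.
    """
    if n_vertices < 3:
        raise ValueError("chain needs >= 3 vertices")
    coords = np.zeros((n_vertices, 3))
    coords[:, 0] = np.arange(n_vertices) * spacing_mm
    faces = np.array([[i, i + 1, i + 2] for i in range(n_vertices - 2)], dtype=np.int64)
    # lift every third vertex by a negligible amount so faces have area
    coords[2::3, 2] = 1e-9
    return SurfaceMesh(coords, faces, hemisphere="synthetic")


def cluster_members(mesh: SurfaceMesh, spec: ClusterSpec) -> np.ndarray:
    """Vertices in the geodesic ball (d <= radius) around the center."""
    if not mesh.cortex_mask[spec.center]:
        raise ValueError(f"cluster center {spec.center} is masked out")
    adj = geodesic_graph(mesh)
    d = dijkstra(adj, directed=False, indices=spec.center, limit=spec.radius_mm)
    return np.flatnonzero((d <= spec.radius_mm) & mesh.cortex_mask)


def simulate_bold(mesh: SurfaceMesh, model: SignalModel) -> VertexTimeSeries:
    """Draw one subject's vertex x timepoint matrix from the factor model.

    Identical (mesh, model) including the seed reproduce the matrix
    bitwise.
    """
    rng = np.random.default_rng(model.seed)
    n_v, n_t = mesh.n_vertices, model.n_timepoints
    x = np.zeros((n_v, n_t))
    shared: dict[int, np.ndarray] = {}
    for spec in model.cluster_specs:
        members = cluster_members(mesh, spec)
        if spec.factor >= 0:
            if spec.factor not in shared:
                shared[spec.factor] = rng.standard_normal(n_t)
            factor = shared[spec.factor]
        else:
            factor = rng.standard_normal(n_t)
        x[members] += spec.weight * factor
    if model.global_weight > 0:
        x += model.global_weight * rng.standard_normal(n_t)
    if model.noise_sd > 0:
        x += model.noise_sd * rng.standard_normal((n_v, n_t))
    return VertexTimeSeries(x, mesh, tr_seconds=2.0)


@dataclass(frozen=True)
class CohortSpec:
    """Generative description of a two-group cohort with planted effects.

    Per subject, the coherence of each planted cluster is

        a_subject = base_weight + gamma[group] * z(score)

    with ``z`` the standardized behavioral score, clipped at zero. Group
    age ranges, the score distribution and covariate draws loosely follow
    an adult-lifespan cognitive study (ages ~19-33 vs ~36-64, IQ-like
    scores at 100 +/- 15, education 8-22 years). The default global
    coupling of 0.4 on unit noise gives a background inter-vertex
    correlation of ~0.14, so the thresholded connectivity network is
    non-degenerate surface-wide, as on real cortex.
    """

    n_per_group: int = 30
    groups: tuple[str, ...] = ("young", "middle")
    score_name: str = "score"
    score_mean: float = 100.0
    score_sd: float = 15.0
    cluster_center: int = 0
    cluster_radius_mm: float = 20.0
    base_weight: float = 0.7
    gamma: Mapping[str, float] | float = 0.2
    global_weight: float = 0.4
    noise_sd: float = 1.0
    n_timepoints: int = 200

    def gamma_of(self, group: str) -> float:
        if isinstance(self.gamma, Mapping):
            return float(self.gamma[group])
        return float(self.gamma)


_AGE_RANGES = {"young": (19.5, 32.8), "middle": (36.6, 64.3)}


def simulate_cohort(
    mesh: SurfaceMesh, spec: CohortSpec, seed: int = 0
) -> tuple[list[VertexTimeSeries], BehaviorTable, dict]:
    """Generate per-subject time series plus a matching behavior table.

    Returns ``(series_list, behavior, manifest)`` where the manifest
    records every generative parameter (including each subject's realized
    cluster weight) for provenance.
    """
    if spec.n_per_group < 5:
        raise ValueError("n_per_group must be >= 5")
    rng = np.random.default_rng(seed)
    rows = []
    series: list[VertexTimeSeries] = []
    realized_weights: list[float] = []
    sub = 0
    for group in spec.groups:
        lo, hi = _AGE_RANGES.get(group, (20.0, 60.0))
        for _ in range(spec.n_per_group):
            sid = f"sub-{sub:03d}"
            age = float(rng.uniform(lo, hi))
            sex = "M" if rng.random() < 0.5 else "F"
            edu = float(np.clip(rng.normal(15.5, 3.0), 8, 22))
            score = float(rng.normal(spec.score_mean, spec.score_sd))
            z = (score - spec.score_mean) / spec.score_sd
            a = max(0.0, spec.base_weight + spec.gamma_of(group) * z)
            realized_weights.append(a)
            model = SignalModel(
                cluster_specs=(
                    ClusterSpec(spec.cluster_center, spec.cluster_radius_mm, a),
                ),
                global_weight=spec.global_weight,
                noise_sd=spec.noise_sd,
                n_timepoints=spec.n_timepoints,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            series.append(simulate_bold(mesh, model))
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "age": age,
                    "sex": sex,
                    "edu": edu,
                    spec.score_name: score,
                }
            )
            sub += 1
    behavior = BehaviorTable(pd.DataFrame(rows), score_columns=(spec.score_name,))
    manifest = {
        "seed": seed,
        "n_per_group": spec.n_per_group,
        "groups": list(spec.groups),
        "score_name": spec.score_name,
        "score_mean": spec.score_mean,
        "score_sd": spec.score_sd,
        "cluster_center": spec.cluster_center,
        "cluster_radius_mm": spec.cluster_radius_mm,
        "base_weight": spec.base_weight,
        "gamma": dict(spec.gamma)
        if isinstance(spec.gamma, Mapping)
        else spec.gamma,
        "global_weight": spec.global_weight,
        "noise_sd": spec.noise_sd,
        "n_timepoints": spec.n_timepoints,
        "realized_cluster_weights": realized_weights,
    }
    return series, behavior, manifest
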