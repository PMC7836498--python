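"""Vertexwise brain-behavior association mapping.

The inference chain: build a group-descriptor style design matrix with
per-group offsets and per-group slopes (the DODS — "different offset,
different slope" — convention), fit an ordinary least-squares model at
every vertex of a cross-subject stack of criticality maps, control the
vertexwise false discovery rate with Benjamini-Hochberg (at alpha/2 per
hemisphere, i.e. Bonferroni over the two hemispheres), extract
edge-connected clusters of significant same-signed vertices with a
minimum size of 5, and summarize each cluster by the partial correlation
of its mean criticality with the behavioral score after removing age,
sex and education.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .core import VifcConfig, VifcMap
from .surface_io import BehaviorTable, SurfaceMesh
from .mesh_geometry import edge_adjacency

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "GlmResult",
    "SigCluster",
    "RankError",
    "build_design",
    "fit_vertexwise",
    "fdr_threshold",
    "extract_clusters",
    "partial_correlation",
]

DEFAULT_MIN_CLUSTER_SIZE = 5


class RankError(ValueError):
    """The design matrix is rank deficient."""


@dataclass(frozen=True)
class ModelSpec:
    """One brain-behavior model: response map + regressors + grouping.

    ``covariates`` default to (age, sex, edu); ``behavioral_regressors``
    is e.g. ``["EI"]``, ``["EP", "SEM", "OEM", "EU"]``, ``["FSIQ"]``,
    ``["GAI", "CPI"]`` or ``["VCI", "PRI", "WMI", "PSI"]``. ``grouping``
    names a categorical column that receives DODS coding (per-level
    offset and per-level slope for every regressor); None fits a single
    group.
    """

    response: str = "vifc"
    covariates: tuple[str, ...] = ("age", "sex", "edu")
    behavioral_regressors: tuple[str, ...] = ()
    grouping: str | None = None

    def __post_init__(self) -> None:
        regs = list(self.covariates) + list(self.behavioral_regressors)
        if len(set(regs)) != len(regs):
            raise ValueError(f"duplicate regressors in {regs}")


@dataclass
class GlmResult:
    """Vertexwise OLS output: betas plus per-contrast t and p maps."""

    betas: np.ndarray  # (V, k)
    tstats: np.ndarray  # (V, n_contrasts)
    pvals: np.ndarray  # (V, n_contrasts)
    contrast_names: list[str]
    column_names: list[str]
    dof: int
    n_subjects: int
    n_skipped_vertices: int = 0

    def contrast_index(self, name: str) -> int:
        return self.contrast_names.index(name)


@dataclass
class SigCluster:
    """An edge-connected set of significant same-signed vertices."""

    vertex_ids: np.ndarray
    hemisphere: str
    sign: str  # "positive" | "negative"
    behavior_name: str = ""
    config: VifcConfig | None = None

    @property
    def size(self) -> int:
        return len(self.vertex_ids)


def _encode_sex(col: pd.Series) -> np.ndarray:
    """Binary 0/1 coding of the sex column, levels in sorted order."""
    levels = sorted(col.astype(str).unique())
    if len(levels) > 2:
        raise ValueError(f"sex has more than two levels: {levels}")
    return col.astype(str).map({lv: float(i) for i, lv in enumerate(levels)}).to_numpy()


def build_design(
    behavior: BehaviorTable, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """DODS design matrix for ``spec`` on ``behavior``.

    With ``g`` group levels and ``m`` regressors the design has
    ``g * (1 + m)`` columns: one offset per level followed by, for each
    regressor in declared order, one slope column per level. All-zero
    columns (a regressor identically zero within a level) are dropped
    with a log note; any remaining collinearity raises :class:`RankError`
    naming the involved columns.
    """
    df = behavior.data
    regressors = list(spec.covariates) + list(spec.behavioral_regressors)
    for name in regressors:
        if name not in df.columns:
            raise ValueError(f"regressor {name!r} not in behavior table")

    if spec.grouping is None:
        levels = ["all"]
        level_of = pd.Series(["all"] * len(df), index=df.index)
    else:
        level_of = df[spec.grouping].astype(str)
        levels = sorted(level_of.unique())
        counts = level_of.value_counts()
        if (counts < 2).any():
            raise ValueError(f"every group level needs >= 2 subjects, got {dict(counts)}")

    reg_values = {}
    for name in regressors:
        if name == "sex":
            reg_values[name] = _encode_sex(df["sex"])
        else:
            reg_values[name] = df[name].to_numpy(dtype=np.float64)

    columns, names = [], []
    for lv in levels:
        ind = (level_of == lv).to_numpy(dtype=np.float64)
        columns.append(ind)
        names.append(f"offset[{lv}]")
    for name in regressors:
        for lv in levels:
            ind = (level_of == lv).to_numpy(dtype=np.float64)
            columns.append(ind * reg_values[name])
            names.append(f"{name}[{lv}]")

    X = np.column_stack(columns)
    nonzero = np.any(X != 0, axis=0)
    if not nonzero.all():
        dropped = [n for n, keep in zip(names, nonzero) if not keep]
        logger.info("build_design: dropping all-zero column(s) %s", dropped)
        X = X[:, nonzero]
        names = [n for n, keep in zip(names, nonzero) if keep]

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a collinear subset via the R factor diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[j] for j in np.flatnonzero(diag < tol)]
        raise RankError(
            f"design matrix rank {rank} < {X.shape[1]} columns; "
            f"collinear column(s): {bad or names}"
        )
    return X, names


def default_contrasts(
    column_names: Sequence[str], spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Contrast matrix for the behavioral regressors.

    For each behavioral regressor: the average of its per-level slope
    columns (the common slope) plus one contrast per level.
    """
    k = len(column_names)
    rows, names = [], []
    for reg in spec.behavioral_regressors:
        idx = [
            j for j, c in enumerate(column_names) if c.split("[")[0] == reg
        ]
        if not idx:
            continue
        avg = np.zeros(k)
        avg[idx] = 1.0 / len(idx)
        rows.append(avg)
        names.append(reg)
        if len(idx) > 1:
            for j in idx:
                row = np.zeros(k)
                row[j] = 1.0
                rows.append(row)
                names.append(column_names[j])
    if not rows:
        raise ValueError("no behavioral regressor columns in the design")
    return np.array(rows), names


def fit_vertexwise(
    maps: Sequence[VifcMap] | np.ndarray,
    design: np.ndarray,
    contrasts: np.ndarray | None = None,
    contrast_names: Sequence[str] | None = None,
    *,
    spec: ModelSpec | None = None,
    column_names: Sequence[str] | None = None,
) -> GlmResult:
    """Ordinary least squares at every vertex of a cross-subject stack.

    ``maps`` is a list of :class:`VifcMap` (subject order matching the
    design rows) or a ready (n_subjects, V) array. Contrasts may be given
    explicitly or derived from ``spec`` + ``column_names`` via
    :func:`default_contrasts`. Vertices with NaN in any subject are
    skipped (NaN in every output) and counted.
    """
    if isinstance(maps, np.ndarray):
        Y = maps.astype(np.float64)
    else:
        Y = np.vstack([m.values for m in maps])
    X = np.asarray(design, dtype=np.float64)
    n, k = X.shape
    if Y.shape[0] != n:
        raise ValueError(f"{Y.shape[0]} maps vs {n} design rows")
    dof = n - k
    if dof <= 0:
        raise ValueError(f"non-positive degrees of freedom: {n} subjects, {k} columns")

    if contrasts is None:
        if spec is None or column_names is None:
            raise ValueError("need explicit contrasts or spec + column_names")
        contrasts, contrast_names = default_contrasts(column_names, spec)
    C = np.atleast_2d(np.asarray(contrasts, dtype=np.float64))
    if contrast_names is None:
        contrast_names = [f"c{j}" for j in range(C.shape[0])]

    V = Y.shape[1]
    ok = ~np.isnan(Y).any(axis=0)
    n_skipped = int((~ok).sum())

    betas = np.full((V, k), np.nan)
    tstats = np.full((V, C.shape[0]), np.nan)
    pvals = np.full((V, C.shape[0]), np.nan)

    if ok.any():
        Yok = Y[:, ok]
        xtx_inv = np.linalg.inv(X.T @ X)
        B = xtx_inv @ X.T @ Yok  # (k, Vok)
        resid = Yok - X @ B
        sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
        betas[ok] = B.T
        cb = C @ B  # (n_contrasts, Vok)
        c_var = np.einsum("ij,jk,ik->i", C, xtx_inv, C)  # (n_contrasts,)
        with np.errstate(invalid="ignore", divide="ignore"):
            se = np.sqrt(c_var[:, None] * sigma2[None, :])
            t = cb / se
        tstats[ok] = t.T
        pvals[ok] = 2.0 * stats.t.sf(np.abs(t), dof).T

    if n_skipped:
        logger.info("fit_vertexwise: skipped %d vertex(es) with NaN values", n_skipped)
    return GlmResult(
        betas=betas,
        tstats=tstats,
        pvals=pvals,
        contrast_names=list(contrast_names),
        column_names=list(column_names) if column_names is not None else [],
        dof=dof,
        n_subjects=n,
        n_skipped_vertices=n_skipped,
    )


def fdr_threshold(
    pvals: np.ndarray, alpha: float = 0.025
) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up significance mask.

    The study convention applies BH at alpha = 0.05/2 within each
    hemisphere (Bonferroni over the two hemispheres). NaN p-values are
    never significant. Returns ``(mask, critical_p)`` where
    ``critical_p`` is the largest rejected p (0.0 when nothing is
    rejected).
    """
    p = np.asarray(pvals, dtype=np.float64)
    mask = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    if not finite.any():
        return mask, 0.0
    rejected, _, _, _ = multipletests(p[finite], alpha=alpha, method="fdr_bh")[:4]
    mask[finite] = rejected
    crit = float(p[mask].max()) if mask.any() else 0.0
    return mask, crit


def extract_clusters(
    mask: np.ndarray,
    tsigns: np.ndarray,
    mesh: SurfaceMesh,
    min_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    *,
    hemisphere: str | None = None,
    behavior_name: str = "",
    config: VifcConfig | None = None,
) -> list[SigCluster]:
    """Edge-connected components of significant same-signed vertices.

    Components smaller than ``min_size`` are discarded. Clusters are
    ordered by size descending, ties broken by the smallest vertex id.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (mesh.n_vertices,):
        raise ValueError("mask length does not match mesh vertex count")
    signs = np.sign(np.asarray(tsigns, dtype=np.float64))
    adj = edge_adjacency(mesh, weighted=False)

    clusters: list[SigCluster] = []
    for sign_value, sign_name in ((1.0, "positive"), (-1.0, "negative")):
        sel = np.flatnonzero(mask & (signs == sign_value) & mesh.cortex_mask)
        if sel.size == 0:
            continue
        sub = adj[sel][:, sel]
        n_comp, labels = connected_components(sub, directed=False)
        for comp in range(n_comp):
            members = sel[labels == comp]
            if members.size >= min_size:
                clusters.append(
                    SigCluster(
                        vertex_ids=np.sort(members),
                        hemisphere=hemisphere or mesh.hemisphere,
                        sign=sign_name,
                        behavior_name=behavior_name,
                        config=config,
                    )
                )
    clusters.sort(key=lambda c: (-c.size, int(c.vertex_ids[0])))
    return clusters


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | pd.DataFrame
) -> tuple[float, float, np.ndarray]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on the covariates (with intercept) by
    OLS; the function returns ``(r, p, residual_pairs)`` where
    ``residual_pairs`` is the (n, 2) array of residuals for scatter
    plotting. Used for cluster-mean criticality vs behavior after
    controlling age, sex and education.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if isinstance(covariates, pd.DataFrame):
        cov = covariates.copy()
        if "sex" in cov.columns:
            cov["sex"] = _encode_sex(cov["sex"])
        Z = cov.to_numpy(dtype=np.float64)
    else:
        Z = np.asarray(covariates, dtype=np.float64)
    if Z.ndim == 1:
        Z = Z[:, None]
    n = len(x)
    if not (len(y) == Z.shape[0] == n):
        raise ValueError("x, y and covariates must have equal length")
    if n <= Z.shape[1] + 2:
        raise ValueError(
            f"need n > n_covariates + 2 (n={n}, covariates={Z.shape[1]})"
        )
    design = np.column_stack([np.ones(n), Z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    r, _ = stats.pearsonr(rx, ry)
    # p-value with dof reduced by the regressed-out covariates
    dof = n - Z.shape[1] - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return float(r), p, np.column_stack([rx, ry])
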