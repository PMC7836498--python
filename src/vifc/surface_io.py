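"""Reading and writing surface meshes, per-vertex data, and behavior tables.

Supported on-disk formats:

* meshes — FreeSurfer binary surfaces, GIFTI ``.surf.gii``, or a CSV pair
  (``vertices.csv`` with x,y,z columns and ``faces.csv`` with v0,v1,v2);
* per-vertex time series and scalar maps — GIFTI ``.func.gii``, MGH/MGZ,
  or CSV matrices (vertices x timepoints);
* behavior/covariate tables — CSV with a mandatory header row.

All coordinates and distances are in millimetres, vertex indexing is
0-based everywhere (including the CSV face files), and CSVs are
comma-separated UTF-8 with a decimal point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SurfaceMesh",
    "VertexTimeSeries",
    "BehaviorTable",
    "MeshFormatError",
    "MeshIntegrityError",
    "ShapeError",
    "DataError",
    "SchemaError",
    "read_mesh",
    "write_mesh",
    "read_timeseries",
    "write_timeseries",
    "read_behavior",
    "read_map",
    "write_map",
]


class MeshFormatError(ValueError):
    """A surface file could not be parsed under the declared format."""


class MeshIntegrityError(ValueError):
    """A parsed mesh violates a structural invariant (e.g. face index range)."""


class ShapeError(ValueError):
    """Per-vertex data does not match the mesh it is bound to."""


class DataError(ValueError):
    """Per-vertex data contains invalid values inside the cortex mask."""


class SchemaError(ValueError):
    """A behavior table is missing a required column."""


@dataclass
class SurfaceMesh:
    """Triangulated cortical surface in mm.

    Parameters
    ----------
    vertex_coords : (V, 3) float array
        Vertex coordinates in millimetres.
    faces : (F, 3) int array
        Triangles as triples of 0-based vertex indices.
    hemisphere : str
        ``"lh"``, ``"rh"`` or ``"synthetic"``.
    cortex_mask : (V,) bool array
        True where a vertex is analyzed; False marks the medial wall or
        other excluded vertices. Defaults to all-true.
    """

    vertex_coords: np.ndarray
    faces: np.ndarray
    hemisphere: str = "synthetic"
    cortex_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.vertex_coords = np.asarray(self.vertex_coords, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertex_coords.ndim != 2 or self.vertex_coords.shape[1] != 3:
            raise MeshIntegrityError(
                f"vertex_coords must be (V, 3), got {self.vertex_coords.shape}"
            )
        if self.n_vertices == 0:
            raise MeshIntegrityError("mesh has no vertices")
        if self.faces.size:
            if self.faces.ndim != 2 or self.faces.shape[1] != 3:
                raise MeshIntegrityError(f"faces must be (F, 3), got {self.faces.shape}")
            if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
                bad = self.faces[
                    ((self.faces < 0) | (self.faces >= self.n_vertices)).any(axis=1)
                ][0]
                raise MeshIntegrityError(
                    f"face {bad.tolist()} references a vertex outside "
                    f"[0, {self.n_vertices})"
                )
            if (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            ).any():
                raise MeshIntegrityError("a face repeats a vertex")
        else:
            self.faces = self.faces.reshape(0, 3)
        if self.cortex_mask is None:
            self.cortex_mask = np.ones(self.n_vertices, dtype=bool)
        else:
            self.cortex_mask = np.asarray(self.cortex_mask, dtype=bool)
            if self.cortex_mask.shape != (self.n_vertices,):
                raise MeshIntegrityError(
                    f"cortex_mask length {self.cortex_mask.shape} does not match "
                    f"{self.n_vertices} vertices"
                )

    @property
    def n_vertices(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with e[0] < e[1]."""
        if not self.n_faces:
            return np.empty((0, 2), dtype=np.int64)
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [0, 2]]]
        )
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def vertex_neighbors(self) -> list[np.ndarray]:
        """One-ring neighbors of every vertex (vertices sharing a face)."""
        nbrs: list[set[int]] = [set() for _ in range(self.n_vertices)]
        for a, b in self.edges():
            nbrs[a].add(int(b))
            nbrs[b].add(int(a))
        return [np.array(sorted(s), dtype=np.int64) for s in nbrs]


@dataclass
class VertexTimeSeries:
    """Per-vertex BOLD matrix bound to a :class:`SurfaceMesh`.

    ``values`` is vertices x timepoints; rows must match the mesh vertex
    count and no NaN may occur inside the cortex mask.
    """

    values: np.ndarray
    mesh: SurfaceMesh
    tr_seconds: float | None = None
    mesh_ref: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ShapeError(f"time series must be 2-D, got shape {self.values.shape}")
        if self.values.shape[0] != self.mesh.n_vertices:
            raise ShapeError(
                f"time series has {self.values.shape[0]} rows but the mesh has "
                f"{self.mesh.n_vertices} vertices"
            )
        if self.n_timepoints < 3:
            raise ShapeError(f"need >= 3 timepoints, got {self.n_timepoints}")
        if np.isnan(self.values[self.mesh.cortex_mask]).any():
            raise DataError("NaN values inside the cortex mask")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class BehaviorTable:
    """Subject-level behavior/covariate table.

    Wraps a DataFrame whose ``subject_id`` column is unique; ``sex`` and
    ``group`` are categorical, every other declared column numeric.
    """

    data: pd.DataFrame
    n_dropped: int = 0
    score_columns: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if "subject_id" not in self.data.columns:
            raise SchemaError("behavior table lacks required column 'subject_id'")
        if self.data["subject_id"].duplicated().any():
            dup = self.data["subject_id"][self.data["subject_id"].duplicated()].iloc[0]
            raise SchemaError(f"duplicate subject_id {dup!r}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def subject_ids(self) -> list[str]:
        return self.data["subject_id"].tolist()


# ---------------------------------------------------------------------------
# meshes

_CATEGORICAL_COLUMNS = ("sex", "group")


def read_mesh(
    path: str | Path,
    format: str,
    *,
    faces_path: str | Path | None = None,
    hemisphere: str = "synthetic",
    cortex_mask: np.ndarray | None = None,
) -> SurfaceMesh:
    """Read a triangulated surface.

    ``format`` is one of ``freesurfer_binary``, ``gifti`` or ``csv_pair``.
    For ``csv_pair``, ``path`` names the vertices CSV (columns x,y,z) and
    ``faces_path`` the faces CSV (columns v0,v1,v2, 0-based).
    """
    path = Path(path)
    if format == "freesurfer_binary":
        try:
            coords, faces = nib.freesurfer.read_geometry(str(path))
        except Exception as exc:  # nibabel raises assorted types
            raise MeshFormatError(f"cannot parse {path} as FreeSurfer surface: {exc}")
    elif format == "gifti":
        img = _load_gifti(path)
        coords = _gifti_array(img, nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"], path)
        faces = _gifti_array(img, nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"], path)
    elif format == "csv_pair":
        if faces_path is None:
            faces_path = path.parent / path.name.replace("vertices", "faces")
        coords = _read_csv_matrix(path, ("x", "y", "z"))
        faces = _read_csv_matrix(Path(faces_path), ("v0", "v1", "v2")).astype(np.int64)
    else:
        raise ValueError(f"unknown mesh format {format!r}")
    return SurfaceMesh(coords, faces, hemisphere=hemisphere, cortex_mask=cortex_mask)


def write_mesh(mesh: SurfaceMesh, path: str | Path, format: str) -> None:
    """Write a mesh in ``freesurfer_binary``, ``gifti`` or ``csv_pair`` format."""
    path = Path(path)
    if format == "freesurfer_binary":
        nib.freesurfer.write_geometry(str(path), mesh.vertex_coords, mesh.faces)
    elif format == "gifti":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
                ),
                nib.gifti.GiftiDataArray(
                    mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
                ),
            ]
        )
        nib.save(img, str(path))
    elif format == "csv_pair":
        faces_path = path.parent / path.name.replace("vertices", "faces")
        pd.DataFrame(mesh.vertex_coords, columns=["x", "y", "z"]).to_csv(
            path, index=False, float_format="%.17g"
        )
        pd.DataFrame(mesh.faces, columns=["v0", "v1", "v2"]).to_csv(
            faces_path, index=False
        )
    else:
        raise ValueError(f"unknown mesh format {format!r}")


def _load_gifti(path: Path) -> nib.gifti.GiftiImage:
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise MeshFormatError(f"cannot parse {path} as GIFTI: {exc}")
    if not isinstance(img, nib.gifti.GiftiImage):
        raise MeshFormatError(f"{path} is not a GIFTI file")
    return img


def _gifti_array(img: nib.gifti.GiftiImage, intent: int, path: Path) -> np.ndarray:
    arrays = [d.data for d in img.darrays if d.intent == intent]
    if not arrays:
        raise MeshFormatError(f"{path} lacks a data array with intent code {intent}")
    return arrays[0]


def _read_csv_matrix(path: Path, columns: Sequence[str]) -> np.ndarray:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise MeshFormatError(f"cannot parse {path} as CSV: {exc}")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise MeshFormatError(f"{path} lacks column(s) {missing}")
    return df[list(columns)].to_numpy()


# ---------------------------------------------------------------------------
# per-vertex data (time series and scalar maps)


def read_timeseries(
    path: str | Path,
    format: str,
    mesh: SurfaceMesh,
    *,
    tr_seconds: float | None = None,
) -> VertexTimeSeries:
    """Read a vertices x timepoints matrix bound to ``mesh``.

    A row/vertex mismatch raises :class:`ShapeError`; data are never
    silently truncated.
    """
    values = _read_vertex_data(Path(path), format)
    if values.ndim == 1:
        values = values[:, None]
    if values.shape[0] != mesh.n_vertices:
        raise ShapeError(
            f"{path}: {values.shape[0]} data rows vs {mesh.n_vertices} mesh vertices"
        )
    return VertexTimeSeries(values, mesh, tr_seconds=tr_seconds, mesh_ref=str(path))


def write_timeseries(ts: VertexTimeSeries, path: str | Path, format: str) -> None:
    _write_vertex_data(ts.values, Path(path), format)


def read_map(path: str | Path, format: str, mesh: SurfaceMesh) -> np.ndarray:
    """Read a per-vertex scalar map; returns a (V,) float array."""
    values = _read_vertex_data(Path(path), format)
    values = np.squeeze(values)
    if values.ndim != 1 or values.shape[0] != mesh.n_vertices:
        raise ShapeError(
            f"{path}: map has shape {values.shape}, mesh has {mesh.n_vertices} vertices"
        )
    return values.astype(np.float64)


def write_map(
    map_values: np.ndarray, mesh: SurfaceMesh, path: str | Path, format: str
) -> None:
    """Write a per-vertex scalar map in ``gifti``, ``mgh`` or ``csv`` format."""
    map_values = np.asarray(map_values, dtype=np.float64)
    if map_values.shape != (mesh.n_vertices,):
        raise ShapeError(
            f"map has shape {map_values.shape}, mesh has {mesh.n_vertices} vertices"
        )
    _write_vertex_data(map_values[:, None], Path(path), format)


def _read_vertex_data(path: Path, format: str) -> np.ndarray:
    if format == "csv":
        df = pd.read_csv(path)
        return df.to_numpy(dtype=np.float64)
    if format == "gifti":
        img = _load_gifti(path)
        return np.column_stack([d.data for d in img.darrays]).astype(np.float64)
    if format == "mgh":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float64)
        # MGH stores surface data as (V, 1, 1[, T])
        return data.reshape(data.shape[0], -1)
    raise ValueError(f"unknown per-vertex data format {format!r}")


def _write_vertex_data(values: np.ndarray, path: Path, format: str) -> None:
    if format == "csv":
        cols = [f"t{i}" for i in range(values.shape[1])]
        pd.DataFrame(values, columns=cols).to_csv(path, index=False, float_format="%.17g")
    elif format == "gifti":
        img = nib.gifti.GiftiImage(
            darrays=[
                nib.gifti.GiftiDataArray(
                    values[:, i].astype(np.float32), intent="NIFTI_INTENT_NONE"
                )
                for i in range(values.shape[1])
            ]
        )
        nib.save(img, str(path))
    elif format == "mgh":
        if values.shape[1] == 1:
            shaped = values.astype(np.float32).reshape(values.shape[0], 1, 1)
        else:
            shaped = values.astype(np.float32).reshape(values.shape[0], 1, 1, -1)
        nib.save(nib.MGHImage(shaped, affine=np.eye(4)), str(path))
    else:
        raise ValueError(f"unknown per-vertex data format {format!r}")


# ---------------------------------------------------------------------------
# behavior tables


def read_behavior(
    path: str | Path, required_columns: Sequence[str] = ()
) -> BehaviorTable:
    """Read a subject behavior/covariate CSV.

    Declared numeric columns are coerced; ``sex`` and ``group`` stay
    categorical. Rows with missing required values are dropped with a
    logged count; a missing required column raises :class:`SchemaError`.
    """
    df = pd.read_csv(Path(path), dtype={"subject_id": str})
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} lacks required column(s): {', '.join(missing)}")
    for col in df.columns:
        if col == "subject_id" or col in _CATEGORICAL_COLUMNS:
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
    required = [c for c in required_columns if c != "subject_id"]
    if required:
        keep = df[required].notna().all(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "read_behavior: dropped %d row(s) with missing required values", n_dropped
            )
        df = df[keep].reset_index(drop=True)
    else:
        n_dropped = 0
    scores = tuple(
        c
        for c in df.columns
        if c not in ("subject_id", "age", "edu") and c not in _CATEGORICAL_COLUMNS
    )
    return BehaviorTable(df, n_dropped=n_dropped, score_columns=scores)
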