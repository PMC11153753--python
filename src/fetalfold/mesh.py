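"""Triangle-mesh data model and I/O.

All meshes live in millimetre world coordinates.  Faces are stored with
0-based indices and counter-clockwise winding when viewed from outside, so
the signed enclosed volume of a closed mesh is positive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import trimesh as _trimesh

MERGE_TOL = 1e-6  # mm; vertices closer than this are merged at load time

__all__ = [
    "TriMesh",
    "VertexField",
    "MeshFormatError",
    "NonManifoldError",
    "read_mesh",
    "write_mesh",
]


class MeshFormatError(ValueError):
    """A mesh file could not be parsed as the named format."""


class NonManifoldError(ValueError):
    """The mesh contains edges shared by a number of faces other than 1 or 2."""


@dataclasses.dataclass
class TriMesh:
    """A triangular surface mesh.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    faces : (m, 3) int array, CCW from outside
    hemisphere : {"left", "right", "none"}
    closed : bool
        True when every edge is shared by exactly two faces.  Volume,
        gyrification and depth operations require a closed mesh.
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: str = "none"
    closed: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    # -- derived connectivity ------------------------------------------------

    def edges(self) -> np.ndarray:
        """Unique undirected edges, (e, 2) sorted within rows."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def face_areas(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        c = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(c, axis=1)

    def area(self) -> float:
        return float(self.face_areas().sum())

    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(), self.faces.copy(), self.hemisphere, self.closed
        )

    def as_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclasses.dataclass
class VertexField:
    """One scalar per mesh vertex (units documented by the producer)."""

    mesh: TriMesh
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if len(self.values) != self.mesh.n_vertices:
            raise ValueError(
                f"field '{self.name}' has {len(self.values)} values for "
                f"{self.mesh.n_vertices} vertices"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"field '{self.name}' contains non-finite values")


# ---------------------------------------------------------------------------
# cleaning and audits
# ---------------------------------------------------------------------------


def _clean(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge duplicate vertices (MERGE_TOL), drop unreferenced vertices and
    degenerate (zero-area) faces."""
    vertices = np.asarray(vertices, dtype=np.float64).reshape(-1, 3)
    faces = np.asarray(faces, dtype=np.int64).reshape(-1, 3)
    # merge duplicates by quantised position
    key = np.round(vertices / MERGE_TOL).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)  # keep original vertex order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    vertices = vertices[np.sort(first)]
    faces = rank[inverse][faces]
    # drop degenerate faces (repeated index or zero area)
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 0] != faces[:, 2])
    )
    faces = faces[distinct]
    c = np.cross(
        vertices[faces[:, 1]] - vertices[faces[:, 0]],
        vertices[faces[:, 2]] - vertices[faces[:, 0]],
    )
    faces = faces[np.linalg.norm(c, axis=1) > 1e-14]
    # drop unreferenced vertices
    used = np.zeros(len(vertices), dtype=bool)
    used[faces] = True
    remap = np.cumsum(used) - 1
    return vertices[used], remap[faces]


def edge_audit(faces: np.ndarray) -> tuple[bool, np.ndarray]:
    """Return (closed, offending_edges).

    ``closed`` is True when every undirected edge is shared by exactly two
    faces; ``offending_edges`` lists edges with valence other than 1 or 2
    (non-manifold).
    """
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    e = np.sort(e, axis=1)
    uniq, counts = np.unique(e, axis=0, return_counts=True)
    bad = uniq[(counts != 1) & (counts != 2)]
    closed = bool(np.all(counts == 2)) and len(bad) == 0
    return closed, bad


# ---------------------------------------------------------------------------
# format I/O
# ---------------------------------------------------------------------------

_TRIMESH_FORMATS = {"off", "obj"}


def _read_vtk_polydata(path: Path) -> tuple[np.ndarray, np.ndarray]:
    # legacy ASCII VTK polydata, POINTS + POLYGONS sections only
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise MeshFormatError(f"{path}: line 1: missing VTK header")
    i = 0
    try:
        points = None
        polys = None
        while i < len(lines):
            tok = lines[i].split()
            if tok and tok[0] == "POINTS":
                n = int(tok[1])
                vals: list[float] = []
                i += 1
                while len(vals) < 3 * n:
                    vals.extend(float(x) for x in lines[i].split())
                    i += 1
                points = np.array(vals).reshape(n, 3)
                continue
            if tok and tok[0] == "POLYGONS":
                m = int(tok[1])
                vals_i: list[int] = []
                i += 1
                while i < len(lines) and len(vals_i) < int(tok[2]):
                    vals_i.extend(int(x) for x in lines[i].split())
                    i += 1
                faces = []
                j = 0
                for _ in range(m):
                    k = vals_i[j]
                    if k != 3:
                        raise MeshFormatError(f"{path}: non-triangular polygon")
                    faces.append(vals_i[j + 1 : j + 4])
                    j += k + 1
                polys = np.array(faces, dtype=np.int64)
                continue
            i += 1
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"{path}: line {i + 1}: {exc}") from exc
    if points is None or polys is None:
        raise MeshFormatError(f"{path}: missing POINTS or POLYGONS section")
    return points, polys


def _write_vtk_polydata(mesh: TriMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nfetalfold surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"POLYGONS {mesh.n_faces} {4 * mesh.n_faces}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in {"off", "obj", "vtk"}:
        raise ValueError(f"unsupported mesh format '{fmt}' (off, obj, vtk)")
    return fmt


def read_mesh(
    path: str | Path, format: str | None = None, hemisphere: str = "none"
) -> TriMesh:
    """Read a surface mesh (OFF, OBJ, or legacy ASCII VTK polydata).

    The mesh is cleaned on load: duplicate vertices are merged at a
    1e-6 mm tolerance, zero-area faces and unreferenced vertices dropped.
    The ``closed`` flag is set by an edge audit; non-manifold edges raise
    :class:`NonManifoldError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt in _TRIMESH_FORMATS:
        try:
            tm = _trimesh.load(str(path), file_type=fmt, process=False, force="mesh")
        except Exception as exc:  # trimesh raises assorted types on bad input
            raise MeshFormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc
        vertices, faces = np.asarray(tm.vertices), np.asarray(tm.faces)
    else:
        vertices, faces = _read_vtk_polydata(path)
    if len(faces) == 0:
        raise MeshFormatError(f"{path}: no faces")
    vertices, faces = _clean(vertices, faces)
    closed, bad = edge_audit(faces)
    if len(bad):
        raise NonManifoldError(
            f"{path}: {len(bad)} non-manifold edges, e.g. {bad[:5].tolist()}"
        )
    return TriMesh(vertices, faces, hemisphere=hemisphere, closed=closed)


def write_mesh(mesh: TriMesh, path: str | Path, format: str | None = None) -> None:
    """Write a mesh; ``read_mesh(write_mesh(m))`` is the identity up to float
    formatting.  OBJ faces are written 1-based per that dialect."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "vtk":
        _write_vtk_polydata(mesh, path)
    elif fmt == "off":
        with open(path, "w") as fh:
            fh.write("OFF\n")
            fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
            for v in mesh.vertices:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    else:  # obj
        with open(path, "w") as fh:
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
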