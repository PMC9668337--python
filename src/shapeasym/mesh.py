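"""Triangle surface meshes: container, I/O and validation.

Vertex indices are 0-based in memory regardless of the on-disk convention.
Coordinates are interpreted in millimetres; no anatomical reorientation is
performed because the spectral descriptors downstream are isometry
invariant.  Supported formats: OFF (ascii, written by this package for
exact text round trips), PLY (ascii and binary little-endian, via
``trimesh``) and the FreeSurfer binary triangle format (via ``nibabel``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh as _trimesh
import nibabel.freesurfer.io as _fsio

log = logging.getLogger(__name__)

_FORMATS = ("freesurfer", "off", "ply")


class MeshFormatError(ValueError):
    """Raised for malformed or non-triangular surface files."""


@dataclass
class TriangleMesh:
    """A triangle surface mesh.

    Parameters
    ----------
    vertices : (V, 3) float array
        Vertex coordinates in mm.
    faces : (F, 3) int array
        0-based vertex-index triples.
    metadata : dict
        Free-form source tag (file path, generator parameters, ...).
    """

    vertices: np.ndarray
    faces: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise ValueError("face indices refer to nonexistent vertices")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(), dict(self.metadata))

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(self.vertices, self.faces, process=False)


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_mesh`; reports, never raises."""

    closed: bool
    manifold: bool
    oriented: bool
    genus: Optional[int]
    boundary_edges: np.ndarray
    nonmanifold_edges: np.ndarray
    n_vertices: int = 0
    n_edges: int = 0
    n_faces: int = 0

    @property
    def ok(self) -> bool:
        return self.closed and self.manifold and self.oriented and self.genus == 0


def _edge_table(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Directed edges, their undirected keys and per-key counts."""
    directed = np.concatenate(
        [faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]], axis=0
    )
    undirected = np.sort(directed, axis=1)
    keys, counts = np.unique(undirected, axis=0, return_counts=True)
    return directed, keys, counts


def validate_mesh(mesh: TriangleMesh) -> ValidationReport:
    """Check closedness, edge-manifoldness, orientation and genus.

    genus is derived from the Euler characteristic ``V - E + F = 2 - 2g``
    and only reported for closed manifold meshes.
    """
    if mesh.n_faces == 0:
        return ValidationReport(False, False, False, None,
                                np.empty((0, 2), int), np.empty((0, 2), int))
    directed, keys, counts = _edge_table(mesh.faces)
    boundary = keys[counts == 1]
    nonmanifold = keys[counts > 2]
    closed = boundary.size == 0 and nonmanifold.size == 0
    manifold = nonmanifold.size == 0
    # consistent orientation: every undirected edge traversed once each way
    dir_keys, dir_counts = np.unique(directed, axis=0, return_counts=True)
    oriented = bool(closed and np.all(dir_counts == 1))
    genus: Optional[int] = None
    n_edges = len(keys)
    if closed and manifold:
        chi = mesh.n_vertices - n_edges + mesh.n_faces
        if (2 - chi) % 2 == 0:
            genus = (2 - chi) // 2
    return ValidationReport(
        closed=closed,
        manifold=manifold,
        oriented=oriented,
        genus=genus,
        boundary_edges=boundary,
        nonmanifold_edges=nonmanifold,
        n_vertices=mesh.n_vertices,
        n_edges=n_edges,
        n_faces=mesh.n_faces,
    )


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    tri = vertices[faces]
    return float(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)


def repair_orientation(mesh: TriangleMesh) -> TriangleMesh:
    """Return a copy with globally consistent winding and outward normals.

    The enclosed-volume sign depends on winding, so meshes are repaired
    (with a logged warning) before any volume computation.
    """
    report = validate_mesh(mesh)
    out = mesh.copy()
    if not report.oriented:
        tm = out.to_trimesh()
        _trimesh.repair.fix_normals(tm)
        out = TriangleMesh(np.asarray(tm.vertices), np.asarray(tm.faces), dict(mesh.metadata))
        log.warning("inconsistent face winding repaired")
    if _signed_volume(out.vertices, out.faces) < 0:
        out.faces = out.faces[:, [0, 2, 1]]
        log.warning("face orientation flipped to make enclosed volume positive")
    return out


# ---------------------------------------------------------------------------
# I/O

def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".off":
        return "off"
    if suffix == ".ply":
        return "ply"
    with open(path, "rb") as fh:
        head = fh.read(4)
    if head[:3] == b"OFF":
        return "off"
    if head[:3] == b"ply":
        return "ply"
    if head[:3] == b"\xff\xff\xfe":
        return "freesurfer"
    if suffix in (".white", ".pial", ".inflated", ".orig", ".sphere"):
        return "freesurfer"
    raise MeshFormatError(f"cannot detect surface format of {path}")


def _read_off(path: Path) -> TriangleMesh:
    with open(path, "r") as fh:
        tokens: list[str] = []
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                tokens.extend(line.split())
    if not tokens or tokens[0] != "OFF":
        raise MeshFormatError(f"{path}: missing OFF header")
    nv, nf = int(tokens[1]), int(tokens[2])
    pos = 4  # skip edge count
    vertices = np.array(tokens[pos:pos + 3 * nv], dtype=np.float64).reshape(nv, 3)
    pos += 3 * nv
    faces = np.empty((nf, 3), dtype=np.int64)
    for i in range(nf):
        cnt = int(tokens[pos])
        if cnt != 3:
            raise MeshFormatError(f"{path}: face {i} has {cnt} vertices, expected 3")
        faces[i] = [int(t) for t in tokens[pos + 1:pos + 4]]
        pos += 1 + cnt
    return TriangleMesh(vertices, faces, {"source": str(path), "format": "off"})


def _write_off(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_faces} 0\n")
        for v in mesh.vertices:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
        for f in mesh.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")


def read_surface(path, fmt: str = "auto") -> TriangleMesh:
    """Read a triangle surface mesh.

    Parameters
    ----------
    path : path-like
    fmt : {"auto", "freesurfer", "off", "ply"}
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if fmt == "auto":
        fmt = _detect_format(path)
    if fmt == "off":
        return _read_off(path)
    if fmt == "ply":
        tm = _trimesh.load(path, file_type="ply", process=False)
        faces = np.asarray(tm.faces)
        if faces.shape[1] != 3:
            raise MeshFormatError(f"{path}: non-triangular PLY faces")
        return TriangleMesh(np.asarray(tm.vertices), faces,
                            {"source": str(path), "format": "ply"})
    if fmt == "freesurfer":
        vertices, faces = _fsio.read_geometry(str(path))
        return TriangleMesh(np.asarray(vertices, dtype=np.float64),
                            np.asarray(faces, dtype=np.int64),
                            {"source": str(path), "format": "freesurfer"})
    raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_surface(mesh: TriangleMesh, path, fmt: str = "auto",
                  encoding: str = "ascii") -> None:
    """Write a mesh; ``encoding`` selects ascii/binary for PLY."""
    path = Path(path)
    if mesh.n_vertices == 0 or mesh.n_faces == 0:
        raise ValueError("refusing to write an empty mesh")
    if fmt == "auto":
        suffix = path.suffix.lower()
        fmt = {"": "freesurfer", ".off": "off", ".ply": "ply"}.get(suffix, "freesurfer")
    if fmt == "off":
        _write_off(mesh, path)
    elif fmt == "ply":
        tm = mesh.to_trimesh()
        data = tm.export(file_type="ply", encoding=encoding)
        if isinstance(data, str):
            data = data.encode()
        path.write_bytes(data)
    elif fmt == "freesurfer":
        _fsio.write_geometry(str(path), mesh.vertices, mesh.faces)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
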