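"""Core mesh data types and STL input/output.

A scan pair is represented as :class:`LabeledMesh` — a triangle surface in
millimetres whose vertices carry a region tag (clinical crown, gingiva, or
other).  STL itself stores neither labels nor units, so labels travel in a JSON
sidecar parallel to the merged vertex order and units are mm by convention
throughout the package.

Parsing and export of the STL container delegate to :mod:`trimesh`; vertex
merging uses an in-package 1e-6 mm grid snap so that the merge tolerance is an
explicit, documented constant far below intraoral-scanner resolution (~10 µm).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .errors import EmptySelectionError, StlFormatError

CROWN = "CROWN"
GINGIVA = "GINGIVA"
OTHER = "OTHER"
LABELS = (CROWN, GINGIVA, OTHER)

#: vertices closer than this (mm) are considered coincident and merged
MERGE_TOL = 1e-6

_BINARY_HEADER = 80
_FACET_RECORD = 50  # 12 float32 + uint16 attribute


@dataclass
class LabeledMesh:
    """Triangle mesh with per-vertex region labels, coordinates in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    labels : (n,) array of strings in ``{CROWN, GINGIVA, OTHER}``
    frame_id : name of the coordinate frame, e.g. ``"STL0"`` or ``"STL1"``
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray
    frame_id: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype="U8").reshape(-1)

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("mesh has non-finite coordinates")
        if len(self.labels) != len(self.vertices):
            raise ValueError("labels must have exactly one entry per vertex")
        unknown = set(np.unique(self.labels)) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            f = self.faces
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("face repeats a vertex")
            # 2-manifold with boundary: each undirected edge on <= 2 faces
            edges = np.sort(
                np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]), axis=1
            )
            _, counts = np.unique(edges, axis=0, return_counts=True)
            if counts.max(initial=0) > 2:
                raise ValueError("mesh is not 2-manifold: an edge is shared by >2 faces")

    # -- convenience --------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def area(self) -> float:
        v = self.vertices
        f = self.faces
        cr = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return float(0.5 * np.linalg.norm(cr, axis=1).sum())

    def copy(self) -> "LabeledMesh":
        return LabeledMesh(
            self.vertices.copy(), self.faces.copy(), self.labels.copy(), self.frame_id
        )

    def with_frame_id(self, frame_id: str) -> "LabeledMesh":
        return replace(self, frame_id=frame_id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LabeledMesh":
        """Return a copy with vertices mapped through ``R v + t``."""
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return LabeledMesh(v, self.faces.copy(), self.labels.copy(), self.frame_id)

    def submesh(self, face_mask: np.ndarray) -> "LabeledMesh":
        """Sub-mesh of the selected faces with vertex indices compacted.

        Kept vertices preserve their relative order, so the operation is
        deterministic and idempotent.
        """
        faces = self.faces[np.asarray(face_mask, dtype=bool)]
        kept = np.unique(faces)
        remap = np.full(len(self.vertices), -1, dtype=np.int64)
        remap[kept] = np.arange(len(kept))
        return LabeledMesh(
            self.vertices[kept], remap[faces], self.labels[kept], self.frame_id
        )

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex normals (unit where defined)."""
        v, f = self.vertices, self.faces
        fn = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        vn = np.zeros_like(v)
        for k in range(3):
            np.add.at(vn, f[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm


@dataclass
class ToothFrame:
    """Local tooth coordinate frame.

    ``axis`` points coronally (apex -> crown); ``section_normal`` is the
    cutting-plane normal, orthogonal to the axis so the plane contains the
    longitudinal axis.
    """

    origin: np.ndarray
    axis: np.ndarray
    section_normal: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.axis = np.asarray(self.axis, dtype=np.float64).reshape(3)
        self.section_normal = np.asarray(self.section_normal, dtype=np.float64).reshape(3)

    def validate(self) -> None:
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector")
        if abs(np.linalg.norm(self.section_normal) - 1.0) > 1e-9:
            raise ValueError("section_normal must be a unit vector")
        if abs(float(self.axis @ self.section_normal)) > 1e-9:
            raise ValueError("axis and section_normal must be orthogonal")

    @property
    def horizontal(self) -> np.ndarray:
        """In-plane horizontal direction; (horizontal, axis, normal) is right-handed."""
        return np.cross(self.axis, self.section_normal)


# ---------------------------------------------------------------------------
# vertex merging
# ---------------------------------------------------------------------------

def merge_duplicate_vertices(
    vertices: np.ndarray, faces: np.ndarray, tol: float = MERGE_TOL
) -> tuple[np.ndarray, np.ndarray]:
    """Merge vertices that fall in the same ``tol``-sized grid cell.

    Exact duplicates (the common case for STL, which stores one vertex record
    per facet corner) always merge; the snap never moves a vertex, it keeps the
    first occurrence's coordinates.
    """
    keys = np.round(np.asarray(vertices, dtype=np.float64) / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    # preserve first-appearance order for determinism
    order = np.argsort(first, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    merged = np.asarray(vertices, dtype=np.float64)[first[order]]
    return merged, rank[inverse][np.asarray(faces, dtype=np.int64)]


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

def _looks_ascii(data: bytes) -> bool:
    head = data[:512].lstrip()
    return head.startswith(b"solid") and b"facet" in data[:4096]


def read_stl(path) -> LabeledMesh:
    """Read an ASCII or binary STL file into a :class:`LabeledMesh`.

    All labels are ``OTHER`` (STL carries none; see :func:`read_labels`).
    Duplicate vertices within 1e-6 mm are merged so faces share indices.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 15:
        raise StlFormatError(f"{path}: file too short ({len(data)} bytes) to be STL")

    if _looks_ascii(data):
        try:
            raw = trimesh.load(
                io.BytesIO(data), file_type="stl", process=False
            )
        except Exception as exc:  # trimesh raises assorted types on bad input
            raise StlFormatError(f"{path}: malformed ASCII STL: {exc}") from exc
    else:
        if len(data) < _BINARY_HEADER + 4:
            raise StlFormatError(
                f"{path}: binary STL truncated before facet count at byte offset 80"
            )
        n_facets = int(np.frombuffer(data, dtype="<u4", count=1, offset=_BINARY_HEADER)[0])
        expected = _BINARY_HEADER + 4 + _FACET_RECORD * n_facets
        if expected != len(data):
            raise StlFormatError(
                f"{path}: binary STL facet count {n_facets} (byte offset 80) implies "
                f"{expected} bytes, file has {len(data)}"
            )
        try:
            raw = trimesh.load(io.BytesIO(data), file_type="stl", process=False)
        except Exception as exc:
            raise StlFormatError(f"{path}: malformed binary STL: {exc}") from exc

    vertices, faces = merge_duplicate_vertices(
        np.asarray(raw.vertices, dtype=np.float64), np.asarray(raw.faces, dtype=np.int64)
    )
    labels = np.full(len(vertices), OTHER, dtype="U8")
    mesh = LabeledMesh(vertices, faces, labels, frame_id=path.stem)
    return mesh


def write_stl(mesh: LabeledMesh, path, dialect: str = "binary") -> Path:
    """Write ``mesh`` to ``path``; labels go to a ``.labels.json`` sidecar.

    ``dialect`` is ``"ascii"`` or ``"binary"``.  Round-tripping through
    :func:`read_stl` reproduces coordinates to 1e-6 mm (binary STL stores
    float32) and face topology up to vertex reindexing.
    """
    if dialect not in ("ascii", "binary"):
        raise ValueError(f"dialect must be 'ascii' or 'binary', got {dialect!r}")
    path = Path(path)
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    payload = tm.export(file_type=file_type)
    if isinstance(payload, str):
        payload = payload.encode()
    path.write_bytes(payload)
    write_labels(mesh, sidecar_path(path))
    return path


def sidecar_path(stl_path) -> Path:
    p = Path(stl_path)
    return p.with_suffix(p.suffix + ".labels.json")


def write_labels(mesh: LabeledMesh, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"labels": mesh.labels.tolist()}))
    return path


def read_labels(path) -> np.ndarray:
    data = json.loads(Path(path).read_text())
    return np.asarray(data["labels"], dtype="U8")


def load_labeled(stl_path, labels_path=None, frame_id: str | None = None) -> LabeledMesh:
    """Read an STL plus its label sidecar (defaults to ``<stl>.labels.json``)."""
    mesh = read_stl(stl_path)
    labels_path = Path(labels_path) if labels_path else sidecar_path(stl_path)
    if labels_path.exists():
        labels = read_labels(labels_path)
        if len(labels) != mesh.n_vertices:
            raise StlFormatError(
                f"{labels_path}: sidecar has {len(labels)} labels for "
                f"{mesh.n_vertices} merged vertices"
            )
        mesh.labels = labels
    if frame_id is not None:
        mesh.frame_id = frame_id
    return mesh


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def crop_region(mesh: LabeledMesh, seed, radius: float) -> LabeledMesh:
    """Sub-mesh of faces whose three vertices lie within ``radius`` of ``seed``.

    This is the declarative, reproducible stand-in for interactive tooth
    segmentation: a seed point (e.g. a tooth apex) and a radius select one
    tooth plus its gingival collar from an arch scan.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    seed = np.asarray(seed, dtype=np.float64).reshape(3)
    inside = np.linalg.norm(mesh.vertices - seed, axis=1) <= radius
    face_mask = inside[mesh.faces].all(axis=1)
    if not face_mask.any():
        raise EmptySelectionError(
            f"crop at seed {seed.tolist()} with radius {radius} mm selected no faces"
        )
    return mesh.submesh(face_mask)
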