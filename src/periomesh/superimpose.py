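"""Crown-restricted rigid best-fit alignment of the re-evaluation scan.

The clinical crown is the only surface assumed unchanged between the baseline
and re-evaluation scans, so the alignment (a) initialises from crown centroids
and principal axes and (b) refines with point-to-point trimmed ICP in which
every CROWN vertex of the moving mesh is matched to its closest point on the
fixed mesh's CROWN triangles.  Gingiva never enters the alignment.

The transform update is the closed-form cross-covariance SVD (Kabsch) solution
with det = +1 enforced (physical scans cannot mirror).  Trimming discards the
largest-distance fraction of correspondences each iteration, which guards
against boundary faces introduced by segmentation cropping and against root
surface newly exposed by recession.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._spatial import TriangleSet
from .errors import AlignmentError
from .mesh_model import CROWN, LabeledMesh


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)

    def validate(self, tol: float = 1e-9) -> None:
        r = self.rotation
        if not np.allclose(r.T @ r, np.eye(3), atol=tol):
            raise ValueError("rotation is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > tol:
            raise ValueError("rotation determinant is not +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(cls, axis, angle_deg: float, translation=(0.0, 0.0, 0.0)):
        axis = np.asarray(axis, dtype=np.float64)
        axis = axis / np.linalg.norm(axis)
        th = np.deg2rad(angle_deg)
        k = np.array(
            [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
        )
        rot = np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)
        return cls(rot, np.asarray(translation, dtype=np.float64))

    @classmethod
    def random(cls, rng: np.random.Generator, max_angle_deg: float, max_translation: float):
        """Uniform random axis, uniform angle/translation magnitudes."""
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0, max_angle_deg)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = direction * rng.uniform(0, max_translation)
        return cls.from_axis_angle(axis, angle, shift)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=np.float64) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first: (self∘other)(x)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def rotation_angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class AlignmentReport:
    """Quality surface of one tooth's best-fit alignment."""

    transform: RigidTransform
    rms_residual: float
    n_correspondences: int
    n_iterations: int
    converged: bool
    rms_history: list = field(default_factory=list)
    init_fallback: bool = False

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.as_matrix().tolist(),
            "rms_residual": self.rms_residual,
            "n_correspondences": self.n_correspondences,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "rms_history": list(self.rms_history),
            "init_fallback": self.init_fallback,
        }


# ---------------------------------------------------------------------------
# crown extraction
# ---------------------------------------------------------------------------

def crown_vertices(mesh: LabeledMesh) -> np.ndarray:
    return mesh.vertices[mesh.labels == CROWN]


def crown_triangles(mesh: LabeledMesh) -> np.ndarray:
    """Triangles whose three vertices are CROWN, in original face order."""
    crown = mesh.labels == CROWN
    keep = crown[mesh.faces].all(axis=1)
    return mesh.vertices[mesh.faces[keep]]


def _require_crown_points(mesh: LabeledMesh, minimum: int = 3) -> np.ndarray:
    pts = crown_vertices(mesh)
    if len(pts) < minimum:
        raise AlignmentError(
            f"mesh {mesh.frame_id!r} has {len(pts)} CROWN vertices; need >= {minimum}"
        )
    return pts


# ---------------------------------------------------------------------------
# initial alignment
# ---------------------------------------------------------------------------

def _principal_basis(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and right-handed eigenvector basis."""
    centered = points - points.mean(axis=0)
    cov = centered.T @ centered / max(len(points) - 1, 1)
    w, v = np.linalg.eigh(cov)
    w = w[::-1]
    v = v[:, ::-1]
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return w, v


_SIGNS = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)


def initial_align(source: LabeledMesh, target: LabeledMesh) -> RigidTransform:
    """Centroid + principal-axes alignment of source crown onto target crown.

    The axis-sign ambiguity is resolved by trying the four proper-rotation
    sign assignments and keeping the one with the lowest crown RMS (nearest
    target crown vertex).  Degenerate principal axes (two eigenvalues equal
    within 1e-6 relative) fall back to a centroid-only translation.
    """
    return _initial_align(source, target)[0]


def _initial_align(source: LabeledMesh, target: LabeledMesh):
    s_pts = _require_crown_points(source)
    t_pts = _require_crown_points(target)
    c_s = s_pts.mean(axis=0)
    c_t = t_pts.mean(axis=0)

    w_s, v_s = _principal_basis(s_pts)
    w_t, v_t = _principal_basis(t_pts)
    scale = max(w_s[0], np.finfo(float).tiny)
    degenerate = (
        (w_s[0] - w_s[1]) / scale < 1e-6
        or (w_s[1] - w_s[2]) / scale < 1e-6
        or (w_t[0] - w_t[1]) / max(w_t[0], np.finfo(float).tiny) < 1e-6
        or (w_t[1] - w_t[2]) / max(w_t[0], np.finfo(float).tiny) < 1e-6
    )
    if degenerate:
        return RigidTransform(np.eye(3), c_t - c_s), True

    tree = cKDTree(t_pts)
    best: RigidTransform | None = None
    best_rms = np.inf
    for signs in _SIGNS:
        rot = v_t @ np.diag(signs) @ v_s.T
        moved = (s_pts - c_s) @ rot.T + c_t
        d, _ = tree.query(moved)
        rms = float(np.sqrt(np.mean(d**2)))
        if rms < best_rms - 1e-15:
            best_rms = rms
            best = RigidTransform(rot, c_t - rot @ c_s)
    assert best is not None
    return best, False


# ---------------------------------------------------------------------------
# trimmed point-to-point ICP
# ---------------------------------------------------------------------------

def _kabsch(x: np.ndarray, y: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping x onto y (det forced to +1)."""
    cx = x.mean(axis=0)
    cy = y.mean(axis=0)
    h = (x - cx).T @ (y - cy)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(rot, cy - rot @ cx)


def icp_crown(
    source: LabeledMesh,
    target: LabeledMesh,
    init: RigidTransform | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    trim_fraction: float = 0.10,
) -> AlignmentReport:
    """Trimmed point-to-point ICP of source CROWN onto target CROWN surface.

    Returns the transform mapping source coordinates into the target frame.
    The RMS over kept correspondences is non-increasing across iterations;
    iteration stops when it improves by less than ``tol`` (mm) or after
    ``max_iter`` iterations.
    """
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    src = _require_crown_points(source)
    tris = crown_triangles(target)
    if len(tris) == 0:
        raise AlignmentError(f"mesh {target.frame_id!r} has no all-CROWN triangles")
    surface = TriangleSet(tris)

    init_fallback = False
    if init is None:
        transform, init_fallback = _initial_align(source, target)
    else:
        transform = init
    n_drop = int(np.floor(trim_fraction * len(src)))
    n_keep = len(src) - n_drop
    if n_keep < 3:
        raise AlignmentError(
            f"only {n_keep} correspondences survive trimming; need >= 3"
        )

    history: list[float] = []
    prev_rms = np.inf
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        moved = transform.apply(src)
        matched, dist, _ = surface.query(moved)
        order = np.argsort(dist, kind="stable")
        kept = order[:n_keep]
        rms = float(np.sqrt(np.mean(dist[kept] ** 2)))
        history.append(rms)
        if prev_rms - rms < tol:
            converged = True
            break
        transform = _kabsch(src[kept], matched[kept])
        prev_rms = rms

    return AlignmentReport(
        transform=transform,
        rms_residual=history[-1],
        n_correspondences=n_keep,
        n_iterations=iterations,
        converged=converged,
        rms_history=history,
        init_fallback=init_fallback,
    )
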