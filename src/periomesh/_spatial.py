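"""Exact closest-point queries from points to a triangle set.

Used by the best-fit (ICP) stage: every source crown vertex is matched to its
closest point on the target crown surface.  Triangles are binned into a
uniform voxel grid by their bounding boxes; a query expands Chebyshev rings of
cells around the query point and stops once the ring lower bound exceeds the
best distance found, which guarantees the returned triangle is the true
closest one.  Ties are broken toward the lowest triangle index.

The inner point-to-triangle test is Ericson's region algorithm ("Real-Time
Collision Detection", 5.1.5), compiled with numba when available; a
vectorised numpy implementation doubles as the brute-force reference and the
no-numba fallback uses a KD-tree on centroids with a circumradius bound.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(fn):
            return fn

        return wrap


# ---------------------------------------------------------------------------
# vectorised numpy implementation (reference / fallback)
# ---------------------------------------------------------------------------

def _pt_tri_closest(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on triangle(s) to point(s); broadcasts on leading axes."""
    a = tri[..., 0, :]
    b = tri[..., 1, :]
    c = tri[..., 2, :]
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("...i,...i->...", ab, ap)
    d2 = np.einsum("...i,...i->...", ac, ap)
    bp = p - b
    d3 = np.einsum("...i,...i->...", ab, bp)
    d4 = np.einsum("...i,...i->...", ac, bp)
    cp_ = p - c
    d5 = np.einsum("...i,...i->...", ab, cp_)
    d6 = np.einsum("...i,...i->...", ac, cp_)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
        denom = va + vb + vc
        v_in = np.where(denom != 0, vb / denom, 0.0)
        w_in = np.where(denom != 0, vc / denom, 0.0)

    # apply region tests in reverse of the sequential algorithm so that the
    # last write (vertex regions) wins exactly as the branching version would
    out = a + v_in[..., None] * ab + w_in[..., None] * ac  # interior default
    out = np.where(((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0))[..., None],
                   b + w_bc[..., None] * (c - b), out)
    out = np.where(((vb <= 0) & (d2 >= 0) & (d6 <= 0))[..., None],
                   a + w_ac[..., None] * ac, out)
    out = np.where(((vc <= 0) & (d1 >= 0) & (d3 <= 0))[..., None],
                   a + v_ab[..., None] * ab, out)
    out = np.where(((d6 >= 0) & (d5 <= d6))[..., None], c, out)
    out = np.where(((d3 >= 0) & (d4 <= d3))[..., None], b, out)
    out = np.where(((d1 <= 0) & (d2 <= 0))[..., None], a, out)
    return out


def closest_point_on_triangles_brute(points: np.ndarray, triangles: np.ndarray,
                                     chunk: int = 256):
    """Reference implementation: test every triangle. O(n_points * n_tris).

    Points are processed in chunks to bound the broadcast temporaries.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    triangles = np.asarray(triangles, dtype=np.float64)
    out_cp = np.empty((len(points), 3))
    out_d = np.empty(len(points))
    out_i = np.empty(len(points), dtype=np.int64)
    for s in range(0, len(points), chunk):
        p = points[s:s + chunk]
        cp = _pt_tri_closest(p[:, None, :], triangles[None, :, :, :])
        d = np.linalg.norm(cp - p[:, None, :], axis=2)
        idx = np.argmin(d, axis=1)  # first (lowest-index) minimum
        rows = np.arange(len(p))
        out_cp[s:s + chunk] = cp[rows, idx]
        out_d[s:s + chunk] = d[rows, idx]
        out_i[s:s + chunk] = idx
    return out_cp, out_d, out_i


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _tri_closest_scalar(px, py, pz, tri):  # pragma: no cover - numba
    ax, ay, az = tri[0, 0], tri[0, 1], tri[0, 2]
    bx, by, bz = tri[1, 0], tri[1, 1], tri[1, 2]
    cx, cy, cz = tri[2, 0], tri[2, 1], tri[2, 2]
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx, by, bz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        t = d1 / (d1 - d3)
        return ax + t * abx, ay + t * aby, az + t * abz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        t = d2 / (d2 - d6)
        return ax + t * acx, ay + t * acy, az + t * acz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and d4 - d3 >= 0.0 and d5 - d6 >= 0.0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return bx + t * (cx - bx), by + t * (cy - by), bz + t * (cz - bz)
    denom = va + vb + vc
    if denom != 0.0:
        v = vb / denom
        w = vc / denom
    else:
        v = 0.0
        w = 0.0
    return (ax + v * abx + w * acx, ay + v * aby + w * acy,
            az + v * abz + w * acz)


@njit(cache=True)
def _grid_query_kernel(points, tris, cell_start, cell_tris, origin, inv_h,
                       nx, ny, nz, out_cp, out_d,
                       out_i):  # pragma: no cover - numba
    n = len(points)
    h = 1.0 / inv_h
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        cx = int(np.floor((px - origin[0]) * inv_h))
        cy = int(np.floor((py - origin[1]) * inv_h))
        cz = int(np.floor((pz - origin[2]) * inv_h))
        # rings needed to cover the whole grid from this point's cell
        max_ring = max(max(cx, nx - 1 - cx), max(cy, ny - 1 - cy),
                       max(cz, nz - 1 - cz))
        if max_ring < 0:
            max_ring = 0
        best_d2 = 1.0e300
        best_t = -1
        bx = by = bz = 0.0
        for ring in range(max_ring + 1):
            # rings 0..ring-1 are done: any triangle not yet encountered has
            # all its cells at index distance >= ring, hence its surface at
            # real distance >= (ring - 1) * h from the point
            if best_t >= 0 and ring >= 1:
                bound = (ring - 1) * h
                if best_d2 <= bound * bound:
                    break
            x0, x1 = cx - ring, cx + ring
            y0, y1 = cy - ring, cy + ring
            z0, z1 = cz - ring, cz + ring
            for ix in range(max(x0, 0), min(x1, nx - 1) + 1):
                ex = ix == x0 or ix == x1
                for iy in range(max(y0, 0), min(y1, ny - 1) + 1):
                    ey = iy == y0 or iy == y1
                    for iz in range(max(z0, 0), min(z1, nz - 1) + 1):
                        if not (ex or ey or iz == z0 or iz == z1):
                            continue  # interior of the ring: already scanned
                        c = (ix * ny + iy) * nz + iz
                        for k in range(cell_start[c], cell_start[c + 1]):
                            t = cell_tris[k]
                            qx, qy, qz = _tri_closest_scalar(px, py, pz, tris[t])
                            d2 = ((qx - px) ** 2 + (qy - py) ** 2
                                  + (qz - pz) ** 2)
                            if d2 < best_d2 or (d2 == best_d2 and t < best_t):
                                best_d2 = d2
                                best_t = t
                                bx, by, bz = qx, qy, qz
        out_cp[i, 0], out_cp[i, 1], out_cp[i, 2] = bx, by, bz
        out_d[i] = np.sqrt(best_d2)
        out_i[i] = best_t


class TriangleSet:
    """Precomputed triangle soup supporting repeated closest-point queries."""

    def __init__(self, triangles: np.ndarray):
        self.triangles = np.ascontiguousarray(
            np.asarray(triangles, dtype=np.float64).reshape(-1, 3, 3)
        )
        if len(self.triangles) == 0:
            raise ValueError("empty triangle set")
        self.centroids = self.triangles.mean(axis=1)
        self.radii = np.linalg.norm(
            self.triangles - self.centroids[:, None, :], axis=2
        ).max(axis=1)
        self.r_max = float(self.radii.max())
        if _HAVE_NUMBA:
            self._build_grid()
        else:
            self.tree = cKDTree(self.centroids)

    # -- voxel grid ---------------------------------------------------------
    def _build_grid(self) -> None:
        tri = self.triangles
        lo = tri.min(axis=1)
        hi = tri.max(axis=1)
        # cell size ~ typical triangle size keeps both the per-cell triangle
        # count and the number of cells per triangle small
        h = max(2.0 * float(np.median(self.radii)), 1e-6)
        self._h = h
        self._origin = lo.min(axis=0)
        span = hi.max(axis=0) - self._origin
        dims = np.maximum(np.ceil(span / h).astype(np.int64), 1)
        self._dims = dims
        nx, ny, nz = int(dims[0]), int(dims[1]), int(dims[2])

        lo_i = np.clip(np.floor((lo - self._origin) / h).astype(np.int64),
                       0, dims - 1)
        hi_i = np.clip(np.floor((hi - self._origin) / h).astype(np.int64),
                       0, dims - 1)
        counts = np.zeros(nx * ny * nz + 1, dtype=np.int64)
        spans = []
        for t in range(len(tri)):
            cells = []
            for ix in range(lo_i[t, 0], hi_i[t, 0] + 1):
                for iy in range(lo_i[t, 1], hi_i[t, 1] + 1):
                    for iz in range(lo_i[t, 2], hi_i[t, 2] + 1):
                        cells.append((ix * ny + iy) * nz + iz)
            spans.append(cells)
            for c in cells:
                counts[c + 1] += 1
        cell_start = np.cumsum(counts)
        cell_tris = np.empty(int(cell_start[-1]), dtype=np.int64)
        cursor = cell_start[:-1].copy()
        for t, cells in enumerate(spans):
            for c in cells:
                cell_tris[cursor[c]] = t
                cursor[c] += 1
        self._cell_start = np.ascontiguousarray(cell_start)
        self._cell_tris = np.ascontiguousarray(cell_tris)

    # -- queries ------------------------------------------------------------
    def query(self, points: np.ndarray):
        """Return (closest_points, distances, triangle_indices)."""
        points = np.ascontiguousarray(
            np.asarray(points, dtype=np.float64).reshape(-1, 3)
        )
        if _HAVE_NUMBA:
            n = len(points)
            cp = np.empty((n, 3))
            dist = np.empty(n)
            idx = np.empty(n, dtype=np.int64)
            _grid_query_kernel(
                points, self.triangles, self._cell_start, self._cell_tris,
                self._origin, 1.0 / self._h,
                int(self._dims[0]), int(self._dims[1]), int(self._dims[2]),
                cp, dist, idx,
            )
            return cp, dist, idx
        return self._query_kdtree(points)

    def _query_kdtree(self, points: np.ndarray):
        """Fallback: KD-tree candidates with a circumradius safety bound."""
        n = len(points)
        m = len(self.triangles)
        cp = np.empty((n, 3))
        dist = np.empty(n)
        tri_idx = np.empty(n, dtype=np.int64)
        pending = np.arange(n)
        k = min(m, 32)
        while len(pending):
            pts = points[pending]
            d_cent, idx = self.tree.query(pts, k=k)
            if k == 1:
                d_cent = d_cent[:, None]
                idx = idx[:, None]
            cand = self.triangles[idx]
            c = _pt_tri_closest(pts[:, None, :], cand)
            d = np.linalg.norm(c - pts[:, None, :], axis=2)
            dmin = d.min(axis=1)
            masked = np.where(d == dmin[:, None], idx, m)
            j = np.argmin(masked, axis=1)
            rows = np.arange(len(pts))
            cp[pending] = c[rows, j]
            dist[pending] = d[rows, j]
            tri_idx[pending] = idx[rows, j]
            if k == m:
                break
            # unexamined triangles have centroid distance >= the kth one
            safe = d_cent[:, -1] - self.r_max >= dmin
            pending = pending[~safe]
            k = min(m, k * 8)
        return cp, dist, tri_idx
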