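"""Compiled exact closest-point-on-surface kernels.

A uniform grid over triangle bounding boxes plus an outward ring search per
query point: cells are visited in increasing Chebyshev ring order and the
search stops once the nearest possible point of the next ring is farther
than the incumbent. Every triangle is registered in every cell its AABB
overlaps, so the search is exact. The point-triangle projection is the
standard barycentric-region case analysis.

This module only contains numerical kernels; :class:`sinusid.distance.
NearestSurface` is the public interface (and falls back to a pure-numpy
path when numba is unavailable).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard speed dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


def build_grid(triangles: np.ndarray, cell_size: float | None = None):
    """CSR cell->triangle table for a uniform grid over the triangle AABBs."""
    tri_lo = triangles.min(axis=1)
    tri_hi = triangles.max(axis=1)
    if cell_size is None:
        # ~2x the median triangle extent keeps cell occupancy near a handful
        ext = np.median(tri_hi - tri_lo, axis=0).max()
        cell_size = max(2.0 * float(ext), 1e-6)
    origin = tri_lo.min(axis=0) - 0.5 * cell_size
    dims = np.maximum(
        1, np.ceil((tri_hi.max(axis=0) - origin) / cell_size).astype(np.int64) + 1
    )
    lo_idx = np.floor((tri_lo - origin) / cell_size).astype(np.int64)
    hi_idx = np.floor((tri_hi - origin) / cell_size).astype(np.int64)
    lo_idx = np.clip(lo_idx, 0, dims - 1)
    hi_idx = np.clip(hi_idx, 0, dims - 1)

    spans = hi_idx - lo_idx + 1
    counts_per_tri = spans.prod(axis=1)
    total = int(counts_per_tri.sum())
    cell_of = np.empty(total, dtype=np.int64)
    tri_of = np.empty(total, dtype=np.int64)
    pos = 0
    stride_y = dims[2]
    stride_x = dims[1] * dims[2]
    for t in range(len(triangles)):
        for ix in range(lo_idx[t, 0], hi_idx[t, 0] + 1):
            for iy in range(lo_idx[t, 1], hi_idx[t, 1] + 1):
                base = ix * stride_x + iy * stride_y
                n = hi_idx[t, 2] + 1 - lo_idx[t, 2]
                cell_of[pos : pos + n] = base + np.arange(lo_idx[t, 2], hi_idx[t, 2] + 1)
                tri_of[pos : pos + n] = t
                pos += n
    order = np.argsort(cell_of, kind="stable")
    cell_of = cell_of[order]
    tri_of = tri_of[order]
    n_cells = int(dims.prod())
    starts = np.searchsorted(cell_of, np.arange(n_cells + 1))
    return origin, float(cell_size), dims, starts.astype(np.int64), tri_of


@njit(cache=True, fastmath=False)
def _pt_tri(px, py, pz, tri):  # pragma: no cover - compiled
    ax, ay, az = tri[0, 0], tri[0, 1], tri[0, 2]
    bx, by, bz = tri[1, 0], tri[1, 1], tri[1, 2]
    cx, cy, cz = tri[2, 0], tri[2, 1], tri[2, 2]
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        qx, qy, qz = ax, ay, az
    else:
        bpx, bpy, bpz = px - bx, py - by, pz - bz
        d3 = abx * bpx + aby * bpy + abz * bpz
        d4 = acx * bpx + acy * bpy + acz * bpz
        if d3 >= 0.0 and d4 <= d3:
            qx, qy, qz = bx, by, bz
        else:
            cpx, cpy, cpz = px - cx, py - cy, pz - cz
            d5 = abx * cpx + aby * cpy + abz * cpz
            d6 = acx * cpx + acy * cpy + acz * cpz
            if d6 >= 0.0 and d5 <= d6:
                qx, qy, qz = cx, cy, cz
            else:
                vc = d1 * d4 - d3 * d2
                if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
                    v = d1 / (d1 - d3)
                    qx, qy, qz = ax + v * abx, ay + v * aby, az + v * abz
                else:
                    vb = d5 * d2 - d1 * d6
                    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
                        w = d2 / (d2 - d6)
                        qx, qy, qz = ax + w * acx, ay + w * acy, az + w * acz
                    else:
                        va = d3 * d6 - d5 * d4
                        if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
                            w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
                            qx = bx + w * (cx - bx)
                            qy = by + w * (cy - by)
                            qz = bz + w * (cz - bz)
                        else:
                            denom = 1.0 / (va + vb + vc)
                            v = vb * denom
                            w = vc * denom
                            qx = ax + abx * v + acx * w
                            qy = ay + aby * v + acy * w
                            qz = az + abz * v + acz * w
    dx, dy, dz = px - qx, py - qy, pz - qz
    return dx * dx + dy * dy + dz * dz, qx, qy, qz


@njit(cache=True)
def query_grid(points, triangles, origin, cell, dims, starts, tri_of):  # pragma: no cover
    n = points.shape[0]
    out_d = np.empty(n)
    out_cp = np.empty((n, 3))
    out_tri = np.empty(n, dtype=np.int64)
    nx, ny, nz = dims[0], dims[1], dims[2]
    stride_x = ny * nz
    stride_y = nz
    max_ring = nx + ny + nz  # generous; loop exits via the distance bound
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        # ring search centered on the UNCLAMPED cell containing the point,
        # so the (R-1)*cell lower bound stays valid even outside the grid;
        # out-of-grid cells in a ring are simply skipped
        cxi = int(np.floor((px - origin[0]) / cell))
        cyi = int(np.floor((py - origin[1]) / cell))
        czi = int(np.floor((pz - origin[2]) / cell))
        off = 0
        for ci, nd in ((cxi, nx), (cyi, ny), (czi, nz)):
            if ci < 0:
                off += -ci
            elif ci >= nd:
                off += ci - nd + 1
        best = 1e300
        best_tri = -1
        bqx = bqy = bqz = 0.0
        for ring in range(max_ring + off + 1):
            if best_tri >= 0:
                lb = (ring - 1) * cell
                if lb > 0.0 and lb * lb > best:
                    break
            x0, x1 = cxi - ring, cxi + ring
            y0, y1 = cyi - ring, cyi + ring
            z0, z1 = czi - ring, czi + ring
            for ix in range(max(x0, 0), min(x1, nx - 1) + 1):
                ex = ix == x0 or ix == x1
                for iy in range(max(y0, 0), min(y1, ny - 1) + 1):
                    ey = iy == y0 or iy == y1
                    for iz in range(max(z0, 0), min(z1, nz - 1) + 1):
                        if not (ex or ey or iz == z0 or iz == z1):
                            continue
                        c = ix * stride_x + iy * stride_y + iz
                        for s in range(starts[c], starts[c + 1]):
                            t = tri_of[s]
                            d2, qx, qy, qz = _pt_tri(px, py, pz, triangles[t])
                            if d2 < best:
                                best = d2
                                best_tri = t
                                bqx, bqy, bqz = qx, qy, qz
        out_d[i] = np.sqrt(best)
        out_cp[i, 0], out_cp[i, 1], out_cp[i, 2] = bqx, bqy, bqz
        out_tri[i] = best_tri
    return out_d, out_cp, out_tri
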