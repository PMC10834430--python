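"""Ray-surface intersection utilities.

Two entry points: a fast vertical-ray batch used for parity voxelization
(candidate triangles found by 2-D proximity binning), and a generic
Moller-Trumbore caster for arbitrary directions used by the cartilage
extrusion.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["vertical_ray_crossings", "ray_cast_first_hit"]


def vertical_ray_crossings(xy: np.ndarray, triangles: np.ndarray):
    """Z-values where upward vertical rays at `xy` cross the triangles.

    Parameters
    ----------
    xy : (R, 2) ray positions in the xy plane
    triangles : (M, 3, 3) triangle corners

    Returns
    -------
    ray_index, z : parallel 1-D arrays of crossings (unsorted).
    Triangles vertical in projection (degenerate xy area) are skipped; call
    sites jitter ray positions so grazing incidence has measure zero.
    """
    a2, b2, c2 = triangles[:, 0, :2], triangles[:, 1, :2], triangles[:, 2, :2]
    cent = (a2 + b2 + c2) / 3.0
    rad = np.maximum(
        np.linalg.norm(a2 - cent, axis=1),
        np.maximum(np.linalg.norm(b2 - cent, axis=1), np.linalg.norm(c2 - cent, axis=1)),
    )
    tree = cKDTree(xy)
    balls = tree.query_ball_point(cent, rad + 1e-9)
    counts = np.fromiter((len(b) for b in balls), dtype=np.int64, count=len(balls))
    if counts.sum() == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    ray_idx = np.concatenate([np.asarray(b, dtype=np.int64) for b in balls if b])
    tri_idx = np.repeat(np.arange(len(triangles)), counts)

    p = xy[ray_idx]
    a, b, c = a2[tri_idx], b2[tri_idx], c2[tri_idx]

    def cross2(u, v):
        return u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]

    det = cross2(b - a, c - a)
    ok = np.abs(det) > 1e-14
    wa = cross2(b - p, c - p)
    wb = cross2(c - p, a - p)
    wc = cross2(a - p, b - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        u, v, w = wa / det, wb / det, wc / det
    inside = ok & (u >= 0) & (v >= 0) & (w >= 0)
    z = (
        u[inside] * triangles[tri_idx[inside], 0, 2]
        + v[inside] * triangles[tri_idx[inside], 1, 2]
        + w[inside] * triangles[tri_idx[inside], 2, 2]
    )
    return ray_idx[inside], z


def ray_cast_first_hit(origins: np.ndarray, directions: np.ndarray, triangles: np.ndarray):
    """First positive-t intersection of each ray with the triangle soup.

    Moller-Trumbore, chunked over rays. Returns (t, hit) where t is inf for
    misses and hit is a boolean array.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=np.float64))
    directions = np.atleast_2d(np.asarray(directions, dtype=np.float64))
    n_rays = len(origins)
    v0 = triangles[:, 0]
    e1 = triangles[:, 1] - v0
    e2 = triangles[:, 2] - v0
    t_best = np.full(n_rays, np.inf)

    chunk = max(1, int(4e6 // max(len(triangles), 1)))
    for start in range(0, n_rays, chunk):
        sl = slice(start, min(start + chunk, n_rays))
        O = origins[sl][:, None, :]
        D = directions[sl][:, None, :]
        pvec = np.cross(D, e2[None, :, :])
        det = np.einsum("rmk,mk->rm", pvec, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv_det = 1.0 / det
            tvec = O - v0[None, :, :]
            u = np.einsum("rmk,rmk->rm", tvec, pvec) * inv_det
            qvec = np.cross(tvec, e1[None, :, :])
            v = np.einsum("rmk,rmk->rm", qvec, D) * inv_det
            t = np.einsum("rmk,mk->rm", qvec, e2) * inv_det
        valid = (
            (np.abs(det) > 1e-14)
            & (u >= -1e-12)
            & (v >= -1e-12)
            & (u + v <= 1 + 1e-12)
            & (t > 1e-9)
        )
        t = np.where(valid, t, np.inf)
        t_best[sl] = t.min(axis=1)
    return t_best, np.isfinite(t_best)
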