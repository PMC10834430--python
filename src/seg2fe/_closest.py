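"""Exact closest-point queries from points to a triangle surface.

Vectorized point-to-triangle projection (Ericson's region classification)
with a conservative KD-tree candidate prune, so queries are exact: for every
query point the returned distance equals the global minimum over all
triangles, not an approximation from a spatial-index leaf.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_point_on_triangles", "SurfaceQuery"]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle i to point i, for paired inputs.

    Parameters
    ----------
    points : (P, 3) float array
    triangles : (P, 3, 3) float array, triangle corners per point

    Returns
    -------
    (P, 3) array of closest points.
    """
    p = np.asarray(points, dtype=np.float64)
    a = triangles[:, 0]
    b = triangles[:, 1]
    c = triangles[:, 2]

    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d4 * d5

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def settle(mask, value):
        fresh = mask & ~done
        out[fresh] = value[fresh]
        done[fresh] = True

    # vertex regions
    settle((d1 <= 0) & (d2 <= 0), a)
    settle((d3 >= 0) & (d4 <= d3), b)
    settle((d6 >= 0) & (d5 <= d6), c)

    with np.errstate(divide="ignore", invalid="ignore"):
        # edge AB
        t = d1 / (d1 - d3)
        settle((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + t[:, None] * ab)
        # edge AC
        t = d2 / (d2 - d6)
        settle((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + t[:, None] * ac)
        # edge BC
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        settle((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0), b + t[:, None] * (c - b))
        # interior
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
        interior = a + v[:, None] * ab + w[:, None] * ac

    out[~done] = interior[~done]
    return out


class SurfaceQuery:
    """Repeated exact nearest-surface-point queries against one triangle mesh.

    The prune is conservative: an upper bound on the surface distance comes
    from the nearest mesh vertex, and every triangle whose centroid ball
    could beat that bound is tested exactly.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray):
        self.vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(faces, dtype=np.int64)
        if len(self.faces) == 0:
            raise ValueError("surface has no faces")
        self._tri = self.vertices[self.faces]  # (M, 3, 3)
        cent = self._tri.mean(axis=1)
        self._radius = np.linalg.norm(self._tri - cent[:, None, :], axis=2).max(axis=1)
        self._rmax = float(self._radius.max())
        # only vertices referenced by faces: an unreferenced vertex would
        # give an upper bound with no triangle inside the candidate ball
        used = np.unique(self.faces)
        self._vtree = cKDTree(self.vertices[used])
        self._ctree = cKDTree(cent)

    def query(self, points: np.ndarray):
        """Return (distances, closest_points, face_indices) for each point."""
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        upper, _ = self._vtree.query(pts, k=1)
        balls = self._ctree.query_ball_point(pts, upper + self._rmax + 1e-12)
        counts = np.fromiter((len(b) for b in balls), dtype=np.int64, count=len(balls))
        cand = np.concatenate([np.asarray(b, dtype=np.int64) for b in balls])
        owner = np.repeat(np.arange(len(pts)), counts)

        closest = closest_point_on_triangles(pts[owner], self._tri[cand])
        d2 = np.einsum("ij,ij->i", pts[owner] - closest, pts[owner] - closest)

        offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
        best_d2 = np.minimum.reduceat(d2, offsets)
        # first pair attaining the per-point minimum
        hits = np.flatnonzero(d2 == best_d2[owner])
        first = hits[np.searchsorted(owner[hits], np.arange(len(pts)))]

        dist = np.sqrt(best_d2)
        return dist, closest[first], cand[first]

    def distance(self, points: np.ndarray) -> np.ndarray:
        return self.query(points)[0]

    def project(self, points: np.ndarray) -> np.ndarray:
        return self.query(points)[1]
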