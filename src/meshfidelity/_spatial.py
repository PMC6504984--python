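"""Exact closest-point queries against a triangle surface.

Candidate triangles are pruned with a KD-tree over triangle centroids plus a
per-triangle circumradius bound, then resolved with an exact vectorised
point-to-triangle projection. The result is identical to brute force over all
triangles (this equivalence is what the test suite checks).
"""
from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import TriangleMesh


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``triangles[i]`` to ``points[i]``, pairwise.

    Vectorised Voronoi-region classification (vertex / edge / interior) of the
    query point relative to each triangle.
    """
    p = np.asarray(points, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
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
    va = d3 * d6 - d5 * d4

    out = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)

    def assign(mask: np.ndarray, value: np.ndarray) -> None:
        nonlocal done
        m = mask & ~done
        out[m] = value[m]
        done |= m

    with np.errstate(divide="ignore", invalid="ignore"):
        assign((d1 <= 0) & (d2 <= 0), a)                        # vertex A
        assign((d3 >= 0) & (d4 <= d3), b)                       # vertex B
        assign((d6 >= 0) & (d5 <= d6), c)                       # vertex C

        v = np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 == 0, 1.0, d1 - d3), 0.0)
        assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + v[:, None] * ab)   # edge AB

        w = np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 == 0, 1.0, d2 - d6), 0.0)
        assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + w[:, None] * ac)   # edge AC

        den = (d4 - d3) + (d5 - d6)
        w = np.where(den != 0, (d4 - d3) / np.where(den == 0, 1.0, den), 0.0)
        assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
               b + w[:, None] * (c - b))                         # edge BC

        den = va + vb + vc
        den = np.where(den == 0, 1.0, den)
        v = vb / den
        w = vc / den
        assign(np.ones(len(p), dtype=bool), a + v[:, None] * ab + w[:, None] * ac)

    return out


class SurfaceQuery:
    """Accelerated exact closest-surface-point queries against a fixed mesh."""

    def __init__(self, mesh: TriangleMesh):
        if mesh.n_faces == 0:
            raise ValueError("cannot build a surface query over an empty mesh")
        self.mesh = mesh
        self._tri = mesh.triangles()
        self._centroids = self._tri.mean(axis=1)
        self._radii = np.linalg.norm(
            self._tri - self._centroids[:, None, :], axis=2).max(axis=1)
        self._rmax = float(self._radii.max())
        self._tree = cKDTree(self._centroids)

    def query(self, points: np.ndarray, chunk: int = 20000
              ) -> tuple[np.ndarray, np.ndarray]:
        """Return (distances, closest_points) for each query point."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        dists = np.empty(len(points))
        closest = np.empty_like(points)
        for start in range(0, len(points), chunk):
            sl = slice(start, start + chunk)
            d, cp = self._query_chunk(points[sl])
            dists[sl] = d
            closest[sl] = cp
        return dists, closest

    def _query_chunk(self, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # Phase 1: exact distance to the triangle whose centroid is nearest
        # gives a per-point upper bound.
        _, seed_idx = self._tree.query(pts)
        seed_cp = closest_point_on_triangles(pts, self._tri[seed_idx])
        ub = np.linalg.norm(pts - seed_cp, axis=1)
        # Phase 2: any triangle that could beat the bound has its centroid
        # within ub + rmax of the query point.
        cand_lists = self._tree.query_ball_point(pts, ub + self._rmax + 1e-12)
        counts = np.fromiter((len(c) for c in cand_lists), dtype=np.int64,
                             count=len(cand_lists))
        flat_tri = np.fromiter(
            (t for lst in cand_lists for t in lst), dtype=np.int64,
            count=int(counts.sum()))
        flat_pts = np.repeat(np.arange(len(pts)), counts)
        cp = closest_point_on_triangles(pts[flat_pts], self._tri[flat_tri])
        d = np.linalg.norm(pts[flat_pts] - cp, axis=1)
        # segment-wise argmin over each point's candidate list
        best_d = ub.copy()
        best_cp = seed_cp.copy()
        if len(flat_pts):
            order = np.lexsort((d, flat_pts))
            pid_sorted = flat_pts[order]
            first = np.ones(len(order), dtype=bool)
            first[1:] = pid_sorted[1:] != pid_sorted[:-1]
            sel = order[first]
            pids = flat_pts[sel]
            better = d[sel] <= best_d[pids]
            best_d[pids[better]] = d[sel][better]
            best_cp[pids[better]] = cp[sel][better]
        return best_d, best_cp
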