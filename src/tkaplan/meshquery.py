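"""Vectorized point-in-mesh and closest-point queries on triangle meshes.

Containment uses the generalized winding number (sum of signed solid
angles; van Oosterom & Strackee), which is robust for the closed, modest
sized meshes used here; closest points evaluate the exact point–triangle
distance against every face.  Both are brute-force over faces but fully
vectorized, with chunking to bound memory.
"""

from __future__ import annotations

import numpy as np
import trimesh

__all__ = ["points_in_mesh", "closest_points_on_mesh"]

_CHUNK = 2_000_000  # point-triangle pairs per block


def points_in_mesh(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Boolean mask of points strictly inside a closed mesh."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles  # (T, 3, 3)
    n_pts, n_tri = len(points), len(tri)
    if n_pts == 0 or n_tri == 0:
        return np.zeros(n_pts, dtype=bool)
    winding = np.zeros(n_pts)
    step = max(1, _CHUNK // max(n_tri, 1))
    for s in range(0, n_pts, step):
        p = points[s : s + step]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=2)
        lb = np.linalg.norm(b, axis=2)
        lc = np.linalg.norm(c, axis=2)
        det = np.einsum("ptk,ptk->pt", a, np.cross(b, c))
        denom = (
            la * lb * lc
            + np.einsum("ptk,ptk->pt", a, b) * lc
            + np.einsum("ptk,ptk->pt", b, c) * la
            + np.einsum("ptk,ptk->pt", c, a) * lb
        )
        winding[s : s + step] = np.arctan2(det, denom).sum(axis=1) / (2 * np.pi)
    return winding > 0.5


def closest_points_on_mesh(
    mesh: trimesh.Trimesh, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact closest surface point for each query point.

    Returns (closest_points, distances, face_indices).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles
    n_pts, n_tri = len(points), len(tri)
    out_pts = np.empty_like(points)
    out_dist = np.empty(n_pts)
    out_face = np.empty(n_pts, dtype=int)
    step = max(1, _CHUNK // max(n_tri, 1))
    for s in range(0, n_pts, step):
        p = points[s : s + step]
        cp = _closest_point_triangles(tri, p)  # (P, T, 3)
        d2 = ((cp - p[:, None, :]) ** 2).sum(axis=2)
        idx = d2.argmin(axis=1)
        rows = np.arange(len(p))
        out_pts[s : s + step] = cp[rows, idx]
        out_dist[s : s + step] = np.sqrt(d2[rows, idx])
        out_face[s : s + step] = idx
    return out_pts, out_dist, out_face


def _closest_point_triangles(tri: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Closest point on each triangle for each query point (P, T, 3).

    Standard region-classification algorithm (Ericson, Real-Time
    Collision Detection) vectorized over the P x T grid.
    """
    a = tri[None, :, 0, :]
    ab = (tri[:, 1] - tri[:, 0])[None, :, :]
    ac = (tri[:, 2] - tri[:, 0])[None, :, :]
    p = points[:, None, :]
    ap = p - a

    d1 = np.einsum("ptk,ptk->pt", np.broadcast_arrays(ab, ap)[0], ap)
    d2 = np.einsum("ptk,ptk->pt", np.broadcast_arrays(ac, ap)[0], ap)

    bp = p - (a + ab)
    d3 = np.einsum("ptk,ptk->pt", np.broadcast_arrays(ab, bp)[0], bp)
    d4 = np.einsum("ptk,ptk->pt", np.broadcast_arrays(ac, bp)[0], bp)

    cp_ = p - (a + ac)
    d5 = np.einsum("ptk,ptk->pt", np.broadcast_arrays(ab, cp_)[0], cp_)
    d6 = np.einsum("ptk,ptk->pt", np.broadcast_arrays(ac, cp_)[0], cp_)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2

    eps = 0.0
    # barycentric candidates, clamped per region
    denom_face = va + vb + vc
    with np.errstate(divide="ignore", invalid="ignore"):
        v_face = np.where(denom_face != 0, vb / denom_face, 0.0)
        w_face = np.where(denom_face != 0, vc / denom_face, 0.0)
        v_ab = np.where((d1 - d3) != 0, d1 / (d1 - d3), 0.0)
        w_ac = np.where((d2 - d6) != 0, d2 / (d2 - d6), 0.0)
        num_bc = d4 - d3
        den_bc = (d4 - d3) + (d5 - d6)
        w_bc = np.where(den_bc != 0, num_bc / den_bc, 0.0)

    v = v_face.copy()
    w = w_face.copy()
    # vertex A region
    mask = (d1 <= eps) & (d2 <= eps)
    v[mask] = 0.0
    w[mask] = 0.0
    # vertex B region
    mb = (d3 >= -eps) & (d4 <= d3)
    v[mb] = 1.0
    w[mb] = 0.0
    # vertex C region
    mc = (d6 >= -eps) & (d5 <= d6)
    v[mc] = 0.0
    w[mc] = 1.0
    # edge AB
    me = (vc <= eps) & (d1 >= -eps) & (d3 <= eps) & ~mask & ~mb & ~mc
    v[me] = np.clip(v_ab[me], 0.0, 1.0)
    w[me] = 0.0
    # edge AC
    mf = (vb <= eps) & (d2 >= -eps) & (d6 <= eps) & ~mask & ~mb & ~mc & ~me
    v[mf] = 0.0
    w[mf] = np.clip(w_ac[mf], 0.0, 1.0)
    # edge BC
    mg = (va <= eps) & ((d4 - d3) >= -eps) & ((d5 - d6) >= -eps) \
        & ~mask & ~mb & ~mc & ~me & ~mf
    wb = np.clip(w_bc[mg], 0.0, 1.0)
    v[mg] = 1.0 - wb
    w[mg] = wb

    return a + v[..., None] * ab + w[..., None] * ac
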