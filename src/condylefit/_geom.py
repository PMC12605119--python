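"""Vectorized ray/mesh and point/mesh primitives.

Brute-force but fully vectorized over (query x triangle) pairs; the meshes in
this pipeline are small (hundreds to a few thousand faces), where the dense
formulation is faster than spatial indexing and has no extra dependencies.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-12


def ray_mesh_intersections(mesh, origins: np.ndarray, directions: np.ndarray):
    """All ray/triangle intersections (Moller-Trumbore, two-sided).

    Returns ``(locations, ray_index, t)`` for every hit with ``t >= 0``
    along the (unit or non-unit) ray directions.
    """
    tri = mesh.triangles  # (m, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0  # (m, 3)
    e2 = v2 - v0
    origins = np.atleast_2d(np.asarray(origins, float))  # (n, 3)
    directions = np.atleast_2d(np.asarray(directions, float))
    if len(directions) == 1 and len(origins) > 1:
        directions = np.broadcast_to(directions, origins.shape)

    d = directions[:, None, :]  # (n, 1, 3)
    p = np.cross(d, e2[None, :, :])  # (n, m, 3)
    det = np.einsum("nmk,mk->nm", p, e1)  # (n, m)
    ok = np.abs(det) > _EPS
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    s = origins[:, None, :] - v0[None, :, :]  # (n, m, 3)
    u = np.einsum("nmk,nmk->nm", s, p) * inv
    q = np.cross(s, e1[None, :, :])
    v = np.einsum("nmk,nk->nm", q, directions) * inv
    t = np.einsum("nmk,mk->nm", q, e2) * inv
    hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1.0 + 1e-9) & (t >= -1e-9)
    ray_idx, tri_idx = np.nonzero(hit)
    tt = t[ray_idx, tri_idx]
    locations = origins[ray_idx] + tt[:, None] * directions[ray_idx]
    return locations, ray_idx, tt


def closest_points_on_mesh(mesh, points: np.ndarray):
    """Closest point on the surface for each query point.

    Returns ``(closest, distance, face_index)``; exact per-triangle closest
    points (Ericson's region decomposition), minimized over all faces.
    """
    tri = mesh.triangles
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab = b - a
    ac = c - a
    pts = np.atleast_2d(np.asarray(points, float))
    n, m = len(pts), len(tri)

    p = pts[:, None, :]  # (n, 1, 3)
    ap = p - a[None]
    d1 = np.einsum("nmk,mk->nm", ap, ab)
    d2 = np.einsum("nmk,mk->nm", ap, ac)
    bp = p - b[None]
    d3 = np.einsum("nmk,mk->nm", bp, ab)
    d4 = np.einsum("nmk,mk->nm", bp, ac)
    cp = p - c[None]
    d5 = np.einsum("nmk,mk->nm", cp, ab)
    d6 = np.einsum("nmk,mk->nm", cp, ac)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom_uv = np.maximum(va + vb + vc, _EPS)

    # barycentric candidates per Ericson's closest-point regions
    u = np.zeros((n, m))
    v = np.zeros((n, m))
    # interior
    u_in = vb / denom_uv
    v_in = vc / denom_uv
    u[:] = u_in
    v[:] = v_in
    # edge AB
    t_ab = np.clip(d1 / np.where(np.abs(d1 - d3) > _EPS, d1 - d3, _EPS), 0.0, 1.0)
    # edge AC
    t_ac = np.clip(d2 / np.where(np.abs(d2 - d6) > _EPS, d2 - d6, _EPS), 0.0, 1.0)
    # edge BC
    num_bc = d4 - d3
    den_bc = (d4 - d3) + (d5 - d6)
    t_bc = np.clip(num_bc / np.where(np.abs(den_bc) > _EPS, den_bc, _EPS), 0.0, 1.0)

    reg_a = (d1 <= 0) & (d2 <= 0)
    reg_b = (d3 >= 0) & (d4 <= d3)
    reg_c = (d6 >= 0) & (d5 <= d6)
    reg_ab = (~reg_a) & (~reg_b) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    reg_ac = (~reg_a) & (~reg_c) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    reg_bc = (~reg_b) & (~reg_c) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)

    u = np.where(reg_bc, 1.0 - t_bc, u)
    v = np.where(reg_bc, t_bc, v)
    u = np.where(reg_ac, 0.0, u)
    v = np.where(reg_ac, t_ac, v)
    u = np.where(reg_ab, t_ab, u)
    v = np.where(reg_ab, 0.0, v)
    u = np.where(reg_c, 0.0, u)
    v = np.where(reg_c, 1.0, v)
    u = np.where(reg_b, 1.0, u)
    v = np.where(reg_b, 0.0, v)
    u = np.where(reg_a, 0.0, u)
    v = np.where(reg_a, 0.0, v)

    closest = a[None] + u[..., None] * ab[None] + v[..., None] * ac[None]
    d2all = np.einsum("nmk,nmk->nm", p - closest, p - closest)
    face = np.argmin(d2all, axis=1)
    rows = np.arange(n)
    return closest[rows, face], np.sqrt(d2all[rows, face]), face
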