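"""Numerical kernels for neighborhood curvature tensors.

These are numba-compiled inner loops: breadth-first collection of the
geodesic-approximating ball around a vertex, analytic clipping of mesh
edges against the bounding sphere, and exact circle/triangle intersection
areas used to normalise the tensor by the neighborhood area.  Everything
here is deterministic: traversal and accumulation orders are fixed by
vertex/edge/face index.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def _clip_length(px, py, pz, qx, qy, qz, cx, cy, cz, r):
    """Length of segment p-q inside the sphere (c, r)."""
    dx = qx - px
    dy = qy - py
    dz = qz - pz
    a = dx * dx + dy * dy + dz * dz
    if a <= 0.0:
        return 0.0
    mx = px - cx
    my = py - cy
    mz = pz - cz
    b = 2.0 * (mx * dx + my * dy + mz * dz)
    cc = mx * mx + my * my + mz * mz - r * r
    disc = b * b - 4.0 * a * cc
    if disc <= 0.0:
        return 0.0
    sq = math.sqrt(disc)
    t0 = (-b - sq) / (2.0 * a)
    t1 = (-b + sq) / (2.0 * a)
    if t0 < 0.0:
        t0 = 0.0
    if t1 > 1.0:
        t1 = 1.0
    if t1 <= t0:
        return 0.0
    return (t1 - t0) * math.sqrt(a)


@njit(cache=True)
def _signed_angle(ux, uy, vx, vy):
    """Signed angle from u to v in (-pi, pi]."""
    return math.atan2(ux * vy - uy * vx, ux * vx + uy * vy)


@njit(cache=True)
def _edge_disk_contrib(px, py, qx, qy, r, r2):
    """Green's-theorem contribution of directed edge p->q to the area of
    (polygon ∩ disk), disk centred at the origin.

    The edge is decomposed into a chord part inside the disk plus signed
    circular sectors sweeping the outside parts.  Sector terms cancel
    pairwise between consecutive edges, so the per-edge sum is exact for
    any simple polygon and is continuous under perturbation (no special
    cases for vertices sitting on the circle).
    """
    dx = qx - px
    dy = qy - py
    a = dx * dx + dy * dy
    if a <= 0.0:
        return 0.0
    b = 2.0 * (px * dx + py * dy)
    cc = px * px + py * py - r2
    disc = b * b - 4.0 * a * cc
    if disc > 0.0:
        sq = math.sqrt(disc)
        t0 = (-b - sq) / (2.0 * a)
        t1 = (-b + sq) / (2.0 * a)
        t0c = t0 if t0 > 0.0 else 0.0
        t1c = t1 if t1 < 1.0 else 1.0
        if t1c > t0c:
            ax = px + t0c * dx
            ay = py + t0c * dy
            bx = px + t1c * dx
            by = py + t1c * dy
            out = 0.5 * (ax * by - ay * bx)
            if t0c > 0.0:
                out += 0.5 * r2 * _signed_angle(px, py, ax, ay)
            if t1c < 1.0:
                out += 0.5 * r2 * _signed_angle(bx, by, qx, qy)
            return out
    # edge entirely outside the disk: pure sector sweep
    return 0.5 * r2 * _signed_angle(px, py, qx, qy)


@njit(cache=True)
def _circle_triangle_area(x0, y0, x1, y1, x2, y2, r):
    """Area of the intersection of a triangle with the disk |x| <= r,
    disk centred at the 2D origin (any triangle winding)."""
    cr = (x1 - x0) * (y2 - y0) - (y1 - y0) * (x2 - x0)
    if cr == 0.0:
        return 0.0
    if cr < 0.0:
        tx = x1
        ty = y1
        x1 = x2
        y1 = y2
        x2 = tx
        y2 = ty
    r2 = r * r
    area = _edge_disk_contrib(x0, y0, x1, y1, r, r2)
    area += _edge_disk_contrib(x1, y1, x2, y2, r, r2)
    area += _edge_disk_contrib(x2, y2, x0, y0, r, r2)
    if area < 0.0:
        area = 0.0
    return area


@njit(cache=True)
def _ball_tensor(
    ci,
    radius,
    margin,
    verts,
    adj_ptr,
    adj_idx,
    ve_ptr,
    ve_idx,
    edges,
    ebeta,
    vf_ptr,
    vf_idx,
    faces,
):
    """Normal-cycle curvature tensor accumulated over the geodesic ball.

    Returns the un-normalised 3x3 tensor (flattened), the clipped
    neighborhood area |B| and the number of contributing edges.
    """
    nv = verts.shape[0]
    cx = verts[ci, 0]
    cy = verts[ci, 1]
    cz = verts[ci, 2]
    r2 = radius * radius
    # vertices are collected out to radius+margin (margin ~ max edge
    # length) so every face or edge intersecting the ball is a candidate;
    # the analytic clipping below restricts exactly to the ball.
    rext2 = (radius + margin) * (radius + margin)

    vmark = np.zeros(nv, np.uint8)
    stack = np.empty(nv, np.int64)
    accepted = np.empty(nv, np.int64)
    na = 0
    top = 0
    stack[top] = ci
    top += 1
    vmark[ci] = 1
    while top > 0:
        top -= 1
        v = stack[top]
        accepted[na] = v
        na += 1
        for k in range(adj_ptr[v], adj_ptr[v + 1]):
            u = adj_idx[k]
            if vmark[u] == 0:
                dx = verts[u, 0] - cx
                dy = verts[u, 1] - cy
                dz = verts[u, 2] - cz
                if dx * dx + dy * dy + dz * dz <= rext2:
                    vmark[u] = 1
                    stack[top] = u
                    top += 1
                else:
                    vmark[u] = 2
    acc = np.sort(accepted[:na])

    M = np.zeros(9)
    emark = np.zeros(edges.shape[0], np.uint8)
    n_edges = 0
    for q in range(na):
        v = acc[q]
        for k in range(ve_ptr[v], ve_ptr[v + 1]):
            e = ve_idx[k]
            if emark[e]:
                continue
            emark[e] = 1
            a = edges[e, 0]
            b = edges[e, 1]
            L = _clip_length(
                verts[a, 0],
                verts[a, 1],
                verts[a, 2],
                verts[b, 0],
                verts[b, 1],
                verts[b, 2],
                cx,
                cy,
                cz,
                radius,
            )
            if L <= 0.0:
                continue
            n_edges += 1
            ex = verts[b, 0] - verts[a, 0]
            ey = verts[b, 1] - verts[a, 1]
            ez = verts[b, 2] - verts[a, 2]
            en = math.sqrt(ex * ex + ey * ey + ez * ez)
            if en <= 0.0:
                continue
            ex /= en
            ey /= en
            ez /= en
            w = ebeta[e] * L
            M[0] += w * ex * ex
            M[1] += w * ex * ey
            M[2] += w * ex * ez
            M[4] += w * ey * ey
            M[5] += w * ey * ez
            M[8] += w * ez * ez
    M[3] = M[1]
    M[6] = M[2]
    M[7] = M[5]

    areaB = 0.0
    fmark = np.zeros(faces.shape[0], np.uint8)
    for q in range(na):
        v = acc[q]
        for k in range(vf_ptr[v], vf_ptr[v + 1]):
            f = vf_idx[k]
            if fmark[f]:
                continue
            fmark[f] = 1
            i0 = faces[f, 0]
            i1 = faces[f, 1]
            i2 = faces[f, 2]
            ux = verts[i1, 0] - verts[i0, 0]
            uy = verts[i1, 1] - verts[i0, 1]
            uz = verts[i1, 2] - verts[i0, 2]
            wx = verts[i2, 0] - verts[i0, 0]
            wy = verts[i2, 1] - verts[i0, 1]
            wz = verts[i2, 2] - verts[i0, 2]
            nxv = uy * wz - uz * wy
            nyv = uz * wx - ux * wz
            nzv = ux * wy - uy * wx
            nn = math.sqrt(nxv * nxv + nyv * nyv + nzv * nzv)
            if nn <= 0.0:
                continue
            nxv /= nn
            nyv /= nn
            nzv /= nn
            dplane = (
                (cx - verts[i0, 0]) * nxv
                + (cy - verts[i0, 1]) * nyv
                + (cz - verts[i0, 2]) * nzv
            )
            if abs(dplane) >= radius:
                continue
            rc = math.sqrt(r2 - dplane * dplane)
            # in-plane orthonormal basis
            un = math.sqrt(ux * ux + uy * uy + uz * uz)
            if un <= 0.0:
                continue
            e1x = ux / un
            e1y = uy / un
            e1z = uz / un
            e2x = nyv * e1z - nzv * e1y
            e2y = nzv * e1x - nxv * e1z
            e2z = nxv * e1y - nyv * e1x
            ox = cx - dplane * nxv
            oy = cy - dplane * nyv
            oz = cz - dplane * nzv
            x0 = (verts[i0, 0] - ox) * e1x + (verts[i0, 1] - oy) * e1y + (
                verts[i0, 2] - oz
            ) * e1z
            y0 = (verts[i0, 0] - ox) * e2x + (verts[i0, 1] - oy) * e2y + (
                verts[i0, 2] - oz
            ) * e2z
            x1 = (verts[i1, 0] - ox) * e1x + (verts[i1, 1] - oy) * e1y + (
                verts[i1, 2] - oz
            ) * e1z
            y1 = (verts[i1, 0] - ox) * e2x + (verts[i1, 1] - oy) * e2y + (
                verts[i1, 2] - oz
            ) * e2z
            x2 = (verts[i2, 0] - ox) * e1x + (verts[i2, 1] - oy) * e1y + (
                verts[i2, 2] - oz
            ) * e1z
            y2 = (verts[i2, 0] - ox) * e2x + (verts[i2, 1] - oy) * e2y + (
                verts[i2, 2] - oz
            ) * e2z
            areaB += _circle_triangle_area(x0, y0, x1, y1, x2, y2, rc)
    return M, areaB, n_edges


@njit(cache=True)
def _tensors_for(
    targets,
    radius,
    margin,
    verts,
    adj_ptr,
    adj_idx,
    ve_ptr,
    ve_idx,
    edges,
    ebeta,
    vf_ptr,
    vf_idx,
    faces,
):
    """Per-vertex neighborhood tensors for the given target vertices."""
    nt = targets.shape[0]
    out = np.zeros((nt, 9))
    areas = np.zeros(nt)
    nedges = np.zeros(nt, np.int64)
    for i in range(nt):
        M, aB, ne = _ball_tensor(
            targets[i],
            radius,
            margin,
            verts,
            adj_ptr,
            adj_idx,
            ve_ptr,
            ve_idx,
            edges,
            ebeta,
            vf_ptr,
            vf_idx,
            faces,
        )
        out[i] = M
        areas[i] = aB
        nedges[i] = ne
    return out, areas, nedges
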