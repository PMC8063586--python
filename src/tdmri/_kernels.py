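"""Numba-compiled geometry and random-walk kernels.

Kernels operate in the substrate frame: sphere packs are cubic lattices of
impermeable spheres (one per cell, edge ``L``), cylinder packs are square
lattices of infinite cylinders along +z. All lengths in µm, times in ms.

Collision handling is specular reflection with an ``eps`` nudge off the
surface after every bounce; a step that exceeds ``max_reflect`` bounces is
rejected (the walker stays put) and counted.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_T_MIN = 1e-12


@njit(cache=False, inline="always")
def _advance_sphere(px, py, pz, sx, sy, sz, L, r, eps, max_reflect):
    """One walker step with specular reflections off a cubic sphere lattice.

    Returns (x, y, z, ok); ok is False if the step was rejected.
    """
    ox, oy, oz = px, py, pz
    for _ in range(max_reflect):
        a = sx * sx + sy * sy + sz * sz
        if a <= 0.0:
            return px, py, pz, True
        ix = np.floor(px / L)
        iy = np.floor(py / L)
        iz = np.floor(pz / L)
        # fast path: the nearest obstacle centre is the own-cell centre
        # (cubic Voronoi); skip the candidate scan when the step cannot
        # reach the nearest membrane.
        rx0 = px - (ix + 0.5) * L
        ry0 = py - (iy + 0.5) * L
        rz0 = pz - (iz + 0.5) * L
        dist0 = np.sqrt(rx0 * rx0 + ry0 * ry0 + rz0 * rz0)
        if np.abs(dist0 - r) > np.sqrt(a):
            return px + sx, py + sy, pz + sz, True
        t_best = 2.0
        bx = 0.0
        by = 0.0
        bz = 0.0
        for di in range(-1, 2):
            for dj in range(-1, 2):
                for dk in range(-1, 2):
                    cx = (ix + di + 0.5) * L
                    cy = (iy + dj + 0.5) * L
                    cz = (iz + dk + 0.5) * L
                    rx = px - cx
                    ry = py - cy
                    rz = pz - cz
                    cq = rx * rx + ry * ry + rz * rz - r * r
                    bq = 2.0 * (sx * rx + sy * ry + sz * rz)
                    disc = bq * bq - 4.0 * a * cq
                    if disc <= 0.0:
                        continue
                    sq = np.sqrt(disc)
                    t1 = (-bq - sq) / (2.0 * a)
                    t2 = (-bq + sq) / (2.0 * a)
                    tt = t1 if t1 > _T_MIN else t2
                    if tt > _T_MIN and tt <= 1.0 and tt < t_best:
                        t_best = tt
                        bx = cx
                        by = cy
                        bz = cz
        if t_best > 1.0:
            return px + sx, py + sy, pz + sz, True
        hx = px + t_best * sx
        hy = py + t_best * sy
        hz = pz + t_best * sz
        nx = (hx - bx) / r
        ny = (hy - by) / r
        nz = (hz - bz) / r
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        nx /= nn
        ny /= nn
        nz /= nn
        rem = 1.0 - t_best
        vx = sx * rem
        vy = sy * rem
        vz = sz * rem
        dot = vx * nx + vy * ny + vz * nz
        vx -= 2.0 * dot * nx
        vy -= 2.0 * dot * ny
        vz -= 2.0 * dot * nz
        # stay on the incoming side of the membrane
        side_out = ((px - bx) ** 2 + (py - by) ** 2 + (pz - bz) ** 2) > r * r
        if side_out:
            px = hx + eps * nx
            py = hy + eps * ny
            pz = hz + eps * nz
        else:
            px = hx - eps * nx
            py = hy - eps * ny
            pz = hz - eps * nz
        sx = vx
        sy = vy
        sz = vz
    return ox, oy, oz, False


@njit(cache=False, inline="always")
def _advance_cylinder(px, py, pz, sx, sy, sz, L, r, eps, max_reflect):
    """One walker step in a square lattice of z-aligned cylinders.

    The z component is free; collisions are resolved in the (x, y) plane.
    """
    ox, oy, oz = px, py, pz
    pz_new = pz + sz
    for _ in range(max_reflect):
        a = sx * sx + sy * sy
        if a <= 0.0:
            return px, py, pz_new, True
        ix = np.floor(px / L)
        iy = np.floor(py / L)
        rx0 = px - (ix + 0.5) * L
        ry0 = py - (iy + 0.5) * L
        dist0 = np.sqrt(rx0 * rx0 + ry0 * ry0)
        if np.abs(dist0 - r) > np.sqrt(a):
            return px + sx, py + sy, pz_new, True
        t_best = 2.0
        bx = 0.0
        by = 0.0
        for di in range(-1, 2):
            for dj in range(-1, 2):
                cx = (ix + di + 0.5) * L
                cy = (iy + dj + 0.5) * L
                rx = px - cx
                ry = py - cy
                cq = rx * rx + ry * ry - r * r
                bq = 2.0 * (sx * rx + sy * ry)
                disc = bq * bq - 4.0 * a * cq
                if disc <= 0.0:
                    continue
                sq = np.sqrt(disc)
                t1 = (-bq - sq) / (2.0 * a)
                t2 = (-bq + sq) / (2.0 * a)
                tt = t1 if t1 > _T_MIN else t2
                if tt > _T_MIN and tt <= 1.0 and tt < t_best:
                    t_best = tt
                    bx = cx
                    by = cy
        if t_best > 1.0:
            return px + sx, py + sy, pz_new, True
        hx = px + t_best * sx
        hy = py + t_best * sy
        nx = (hx - bx) / r
        ny = (hy - by) / r
        nn = np.sqrt(nx * nx + ny * ny)
        nx /= nn
        ny /= nn
        rem = 1.0 - t_best
        vx = sx * rem
        vy = sy * rem
        dot = vx * nx + vy * ny
        vx -= 2.0 * dot * nx
        vy -= 2.0 * dot * ny
        side_out = ((px - bx) ** 2 + (py - by) ** 2) > r * r
        if side_out:
            px = hx + eps * nx
            py = hy + eps * ny
        else:
            px = hx - eps * nx
            py = hy - eps * ny
        sx = vx
        sy = vy
    return ox, oy, oz, False


@njit(cache=False)
def advance_one(geom, px, py, pz, sx, sy, sz, L, r, eps, max_reflect):
    """Single-step dispatcher: geom 0 = free, 1 = sphere pack, 2 = cylinder."""
    if geom == 0:
        return px + sx, py + sy, pz + sz, True
    if geom == 1:
        return _advance_sphere(px, py, pz, sx, sy, sz, L, r, eps, max_reflect)
    return _advance_cylinder(px, py, pz, sx, sy, sz, L, r, eps, max_reflect)


def walk_accumulate(pos0, n_steps, sigma, grads, dt, geom, L, r, eps,
                    max_reflect, rng, max_batch_bytes=134_217_728):
    """Batched driver around :func:`walk_batch`.

    Draws Gaussian steps (scale ``sigma`` per axis) from ``rng`` in walker
    batches sized to bound memory, and concatenates the per-batch results.
    """
    n = pos0.shape[0]
    batch = max(1, int(max_batch_bytes // (n_steps * 3 * 8)))
    qvecs = []
    finals = []
    n_rejected = 0
    for lo in range(0, n, batch):
        hi = min(n, lo + batch)
        steps = rng.standard_normal((hi - lo, n_steps, 3)) * sigma
        q, f, rej = walk_batch(pos0[lo:hi], steps, grads, dt, geom, L, r,
                               eps, max_reflect)
        qvecs.append(q)
        finals.append(f)
        n_rejected += rej
    return np.concatenate(qvecs), np.concatenate(finals), n_rejected


@njit(cache=False)
def walk_batch(pos0, steps, grads, dt, geom, L, r, eps, max_reflect):
    """Random walk of one walker batch with q-vector accumulation.

    pos0 : (n, 3) start positions
    steps : (n, n_steps, 3) pre-drawn Gaussian steps, µm
    grads : (n_wave, n_steps) effective gradient samples, T/m (zero-padded)

    Returns (qvec (n, n_wave, 3), final_pos (n, 3), n_rejected).
    The q-vectors are Σ_i g_w(t_i)·x(t_i)·dt with x the *post-step* position,
    so the spin phase along direction u is GAMMA_PHASE · (q · u).
    """
    n = pos0.shape[0]
    n_steps = steps.shape[1]
    n_wave = grads.shape[0]
    qvec = np.empty((n, n_wave, 3))
    final = np.empty((n, 3))
    traj = np.empty((n_steps, 3))
    n_rejected = 0
    for j in range(n):
        px = pos0[j, 0]
        py = pos0[j, 1]
        pz = pos0[j, 2]
        for i in range(n_steps):
            sx = steps[j, i, 0]
            sy = steps[j, i, 1]
            sz = steps[j, i, 2]
            if geom == 0:
                px += sx
                py += sy
                pz += sz
            elif geom == 1:
                px, py, pz, ok = _advance_sphere(
                    px, py, pz, sx, sy, sz, L, r, eps, max_reflect)
                if not ok:
                    n_rejected += 1
            else:
                px, py, pz, ok = _advance_cylinder(
                    px, py, pz, sx, sy, sz, L, r, eps, max_reflect)
                if not ok:
                    n_rejected += 1
            traj[i, 0] = px
            traj[i, 1] = py
            traj[i, 2] = pz
        qvec[j] = np.dot(grads, traj) * dt
        final[j, 0] = px
        final[j, 1] = py
        final[j, 2] = pz
    return qvec, final, n_rejected
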