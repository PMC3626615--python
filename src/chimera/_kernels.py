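"""Compiled inner loops (numba) for the broad phase and contact forces.

These implement exactly the same voxel-grid neighbor search and
discrete-element force law as the reference numpy routines in
:mod:`chimera.physics`; they exist because the pair loops dominate the
step cost.  When numba is unavailable the callers fall back to the
numpy implementations.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if len(args) == 1 and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _pairs_kernel(pos, radius, ox, oy, oz, voxel, D, cutoff):  # pragma: no cover - compiled
    n = pos.shape[0]
    nv = D * D * D
    key = np.empty(n, np.int64)
    count = np.zeros(nv + 1, np.int64)
    for i in range(n):
        a = int((pos[i, 0] - ox) / voxel)
        b = int((pos[i, 1] - oy) / voxel)
        c = int((pos[i, 2] - oz) / voxel)
        if a < 0:
            a = 0
        elif a >= D:
            a = D - 1
        if b < 0:
            b = 0
        elif b >= D:
            b = D - 1
        if c < 0:
            c = 0
        elif c >= D:
            c = D - 1
        k = (a * D + b) * D + c
        key[i] = k
        count[k + 1] += 1
    for v in range(nv):
        count[v + 1] += count[v]
    order = np.empty(n, np.int64)
    fill = count[:-1].copy()
    for i in range(n):
        order[fill[key[i]]] = i
        fill[key[i]] += 1
    cut2 = cutoff * cutoff

    # two passes: count, then fill
    total = 0
    for ph in range(2):
        if ph == 1:
            I = np.empty(total, np.int64)
            J = np.empty(total, np.int64)
            DIST = np.empty(total, np.float64)
        m = 0
        for i in range(n):
            k = key[i]
            az = k % D
            ay = (k // D) % D
            ax = k // (D * D)
            for dx in range(-1, 2):
                vx = ax + dx
                if vx < 0 or vx >= D:
                    continue
                for dy in range(-1, 2):
                    vy = ay + dy
                    if vy < 0 or vy >= D:
                        continue
                    for dz in range(-1, 2):
                        vz = az + dz
                        if vz < 0 or vz >= D:
                            continue
                        vk = (vx * D + vy) * D + vz
                        for q in range(count[vk], count[vk + 1]):
                            j = order[q]
                            if j <= i:
                                continue
                            d0 = pos[i, 0] - pos[j, 0]
                            d1 = pos[i, 1] - pos[j, 1]
                            d2 = pos[i, 2] - pos[j, 2]
                            dd = d0 * d0 + d1 * d1 + d2 * d2
                            if dd <= cut2:
                                if ph == 1:
                                    I[m] = i
                                    J[m] = j
                                    DIST[m] = np.sqrt(dd)
                                m += 1
        if ph == 0:
            total = m
    return I, J, DIST


@njit(cache=True)
def _contact_forces_kernel(
    pos, vel, radius, I, J, dist, k_spring, k_damp, k_shear, eps, n_exp, F_int
):  # pragma: no cover - compiled
    for p in range(I.shape[0]):
        i = I[p]
        j = J[p]
        d = dist[p]
        contact = radius[i] + radius[j]
        if d >= contact or d <= 0.0:
            continue
        inv = 1.0 / d
        nx = (pos[i, 0] - pos[j, 0]) * inv
        ny = (pos[i, 1] - pos[j, 1]) * inv
        nz = (pos[i, 2] - pos[j, 2]) * inv
        vx = vel[i, 0] - vel[j, 0]
        vy = vel[i, 1] - vel[j, 1]
        vz = vel[i, 2] - vel[j, 2]
        vn = vx * nx + vy * ny + vz * nz
        overlap = contact - d
        soft = eps * n_exp * contact**n_exp / d ** (n_exp + 1.0)
        cap = k_spring * contact
        if soft > cap:
            soft = cap
        fn = k_spring * overlap + soft - k_damp * vn
        # tangential (shear) component of the relative velocity
        tx = vx - vn * nx
        ty = vy - vn * ny
        tz = vz - vn * nz
        fx = fn * nx - k_shear * tx
        fy = fn * ny - k_shear * ty
        fz = fn * nz - k_shear * tz
        F_int[i, 0] += fx
        F_int[i, 1] += fy
        F_int[i, 2] += fz
        F_int[j, 0] -= fx
        F_int[j, 1] -= fy
        F_int[j, 2] -= fz


def pairs_within(pos: np.ndarray, radius: np.ndarray, origin, voxel: float, dims: int, cutoff: float):
    """Voxel-grid pair search: all (i, j, dist) with dist <= cutoff, i < j."""
    return _pairs_kernel(
        np.ascontiguousarray(pos),
        radius,
        float(origin[0]),
        float(origin[1]),
        float(origin[2]),
        float(voxel),
        int(dims),
        float(cutoff),
    )


def contact_forces(pos, vel, radius, I, J, dist, p, F_int):
    """Accumulate DEM contact forces for candidate pairs into F_int."""
    _contact_forces_kernel(
        np.ascontiguousarray(pos),
        np.ascontiguousarray(vel),
        radius,
        I,
        J,
        dist,
        float(p.k_spring),
        float(p.k_damp),
        float(p.k_shear),
        float(p.soft_core_strength),
        float(p.soft_core_exponent),
        F_int,
    )
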