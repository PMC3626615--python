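"""Mechanics: forces, adhesion springs, broad phase, and the time step.

Every body obeys m dv/dt = F with F the sum of a shared random
environmental force, gravity, viscous drag, discrete-element contact
forces with a soft-core repulsion, and (for cells only) Hookean adhesion
spring forces to the walls and to linked cells.  Integration is
semi-implicit Euler: the velocity is updated from the force first and
the position from the *new* velocity.

Collision candidates come from a uniform voxel grid covering the box: a
pair can only interact if their voxels are identical or adjacent, so the
27-voxel neighborhood search is exact for any cutoff up to the voxel
size.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .config import AdhesionParams, PhysicsParams
from .state import Body, SimulationState

__all__ = [
    "WALL_NAMES",
    "NumericalInstabilityError",
    "env_force",
    "drag_force",
    "pair_collision_force",
    "voxel_index",
    "Grid",
    "candidate_pairs",
    "wall_distance",
    "wall_distances",
    "update_wall_springs",
    "wall_spring_force",
    "update_cell_springs",
    "cell_spring_force",
    "resolve_wall_bounce",
    "total_cell_force",
    "total_particle_force",
    "compute_forces",
    "integrate",
]

# Fixed wall ordering (also the tie-break order for the closest wall):
# floor, ceiling, then the four sides.
WALL_NAMES = ("floor", "ceiling", "x_minus", "x_plus", "y_minus", "y_plus")
_WALL_NORMALS = np.array(
    [
        [0.0, 0.0, 1.0],   # floor z = -L
        [0.0, 0.0, -1.0],  # ceiling z = 0
        [1.0, 0.0, 0.0],   # x = 0
        [-1.0, 0.0, 0.0],  # x = L
        [0.0, 1.0, 0.0],   # y = 0
        [0.0, -1.0, 0.0],  # y = L
    ]
)


class NumericalInstabilityError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# environmental forces


def env_force(rng: np.random.Generator, sigma: float) -> np.ndarray:
    """One shared draw of the homogeneous random forcing, sigma * xi.

    Each component of xi is i.i.d. uniform on [-1, 1]; the same vector is
    applied to every body in the step, modelling spatially homogeneous
    fluid fluctuations (no small-scale eddies).
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    xi = rng.uniform(-1.0, 1.0, size=3)
    return sigma * xi


def drag_force(v: np.ndarray, gamma: float) -> np.ndarray:
    """Viscous drag -gamma * v."""
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    return -gamma * np.asarray(v, dtype=float)


# ---------------------------------------------------------------------------
# collisions


def _collision_kernel(
    dvec: np.ndarray,
    dist: np.ndarray,
    vrel: np.ndarray,
    contact: np.ndarray,
    p: PhysicsParams,
) -> np.ndarray:
    """DEM force on body i of each overlapping pair (i, j).

    dvec = r_i - r_j, vrel = v_i - v_j, contact = R_i + R_j; callers must
    have filtered to dist < contact and dist > 0.  The force is the sum of
    a linear repulsive spring on the overlap, normal damping, tangential
    shear damping, and the gradient of the truncated soft-core potential
    U(d) = eps * (contact / d) ** n.  It is antisymmetric by construction.
    """
    n_hat = dvec / dist[:, None]
    overlap = contact - dist
    vn = np.einsum("ij,ij->i", vrel, n_hat)
    v_norm = vn[:, None] * n_hat
    v_tan = vrel - v_norm
    eps, n_exp = p.soft_core_strength, p.soft_core_exponent
    soft = eps * n_exp * contact**n_exp / dist ** (n_exp + 1)
    # The gradient diverges as d -> 0; deep interpenetrations (e.g. two
    # particles injected almost on top of each other) would otherwise kick
    # velocities beyond the stable step.  Cap it at the full-overlap force
    # of the linear contact spring.
    np.minimum(soft, p.k_spring * contact, out=soft)
    f = (p.k_spring * overlap + soft)[:, None] * n_hat
    f -= p.k_damp * v_norm
    f -= p.k_shear * v_tan
    return f


def pair_collision_force(a: Body, b: Body, p: PhysicsParams) -> np.ndarray:
    """Contact force exerted on ``a`` by ``b``; zero when not interpenetrating."""
    dvec = (a.position - b.position)[None, :]
    dist = np.linalg.norm(dvec, axis=1)
    contact = np.array([a.radius + b.radius])
    if dist[0] >= contact[0]:
        return np.zeros(3)
    if dist[0] == 0.0:
        raise ValueError(
            "coincident body centers: the integrator resolves these with a "
            "seeded jitter before force evaluation"
        )
    vrel = (a.velocity - b.velocity)[None, :]
    return _collision_kernel(dvec, dist, vrel, contact, p)[0]


# ---------------------------------------------------------------------------
# broad phase


def voxel_index(pos: np.ndarray, p: PhysicsParams) -> tuple[int, int, int]:
    """Integer voxel triple floor((pos - origin) / voxel_size)."""
    pos = np.asarray(pos, dtype=float)
    _check_inside(pos[None, :], p)
    rel = (pos - np.asarray(p.grid_origin)) / p.voxel_size
    return tuple(int(v) for v in np.floor(rel))


def _check_inside(P: np.ndarray, p: PhysicsParams) -> None:
    L = p.box_side
    ok = (
        (P[:, 0] >= 0) & (P[:, 0] <= L)
        & (P[:, 1] >= 0) & (P[:, 1] <= L)
        & (P[:, 2] >= -L) & (P[:, 2] <= 0)
    )
    if not ok.all():
        raise ValueError("position outside the box volume (integration bug?)")


class Grid:
    """Uniform voxel grid over the container, rebuilt from scratch each step.

    Bodies are binned by ``floor((pos - origin) / voxel_size)``; candidate
    interaction pairs are drawn from identical or adjacent voxels only.
    """

    def __init__(self, p: PhysicsParams, positions: np.ndarray):
        self.p = p
        self.voxel_size = p.voxel_size
        self.origin = np.asarray(p.grid_origin, dtype=float)
        self.dims = max(1, int(np.ceil(p.box_side / p.voxel_size - 1e-12)))
        _check_inside(positions, p)
        rel = (positions - self.origin) / self.voxel_size
        idx3 = np.floor(rel).astype(np.int64)
        np.clip(idx3, 0, self.dims - 1, out=idx3)  # boundary-exact positions
        D = self.dims
        self.keys = (idx3[:, 0] * D + idx3[:, 1]) * D + idx3[:, 2]
        self.idx3 = idx3
        self.order = np.argsort(self.keys, kind="stable")
        skeys = self.keys[self.order]
        self.ukeys, self.starts, self.counts = np.unique(
            skeys, return_index=True, return_counts=True
        )
        self.n = positions.shape[0]

    def voxel_of(self, i: int) -> tuple[int, int, int]:
        return tuple(int(v) for v in self.idx3[i])

    def neighbor_candidates(self, i: int) -> np.ndarray:
        """Indices of all bodies in the 27-voxel neighborhood of body i
        (excluding i itself); a superset of its true interaction partners."""
        D = self.dims
        cx, cy, cz = self.idx3[i]
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    nx, ny, nz = cx + dx, cy + dy, cz + dz
                    if not (0 <= nx < D and 0 <= ny < D and 0 <= nz < D):
                        continue
                    key = (nx * D + ny) * D + nz
                    g = np.searchsorted(self.ukeys, key)
                    if g < len(self.ukeys) and self.ukeys[g] == key:
                        s, c = self.starts[g], self.counts[g]
                        out.append(self.order[s : s + c])
        if not out:
            return np.empty(0, dtype=np.int64)
        cand = np.concatenate(out)
        return cand[cand != i]

    def _candidate_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        D = self.dims
        order, starts, counts, uk = self.order, self.starts, self.counts, self.ukeys
        I_parts: list[np.ndarray] = []
        J_parts: list[np.ndarray] = []
        # intra-voxel combinations, vectorized over voxels of equal occupancy
        occupied = counts > 1
        for c in np.unique(counts[occupied]).tolist():
            sel = np.flatnonzero(counts == c)
            block = order[starts[sel][:, None] + np.arange(c)]
            ii, jj = _triu_cached(c)
            I_parts.append(block[:, ii].ravel())
            J_parts.append(block[:, jj].ravel())
        # cross-voxel pairs over the 13 lexicographically-positive offsets
        cz = uk % D
        cy = (uk // D) % D
        cx = uk // (D * D)
        for dx, dy, dz in _HALF_OFFSETS:
            nx, ny, nz = cx + dx, cy + dy, cz + dz
            valid = (nx >= 0) & (nx < D) & (ny >= 0) & (ny < D) & (nz >= 0) & (nz < D)
            if not valid.any():
                continue
            src = np.flatnonzero(valid)
            nkey = (nx[src] * D + ny[src]) * D + nz[src]
            loc = np.searchsorted(uk, nkey)
            loc_c = np.minimum(loc, uk.size - 1)
            found = uk[loc_c] == nkey
            if not found.any():
                continue
            g1 = src[found]
            g2 = loc_c[found]
            i_out, j_out = _cross_pairs(order, starts, counts, g1, g2)
            I_parts.append(i_out)
            J_parts.append(j_out)
        if not I_parts:
            e = np.empty(0, dtype=np.int64)
            return e, e.copy()
        return np.concatenate(I_parts), np.concatenate(J_parts)


_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _triu_cached(c: int) -> tuple[np.ndarray, np.ndarray]:
    if c not in _TRIU_CACHE:
        _TRIU_CACHE[c] = np.triu_indices(c, k=1)
    return _TRIU_CACHE[c]


# The 13 lexicographically-positive neighbor offsets: each adjacent voxel
# pair is visited exactly once.
_HALF_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


def _cross_pairs(order, starts, counts, g1, g2):
    """All cross products of members of matched voxel-group pairs, vectorized."""
    c1 = counts[g1]
    c2 = counts[g2]
    sizes = c1 * c2
    total = int(sizes.sum())
    if total == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy()
    ends = np.cumsum(sizes)
    t = np.arange(total)
    k = np.searchsorted(ends, t, side="right")
    local = t - (ends[k] - sizes[k])
    a = local // c2[k]
    b = local % c2[k]
    i_out = order[starts[g1][k] + a]
    j_out = order[starts[g2][k] + b]
    return i_out, j_out


def candidate_pairs(grid: Grid, positions: np.ndarray, cutoff: float | None = None):
    """Pairs (i, j, dist) with dist <= cutoff, from the voxel broad phase."""
    if cutoff is None:
        cutoff = grid.voxel_size
    if cutoff > grid.voxel_size + 1e-12:
        raise ValueError("pair cutoff exceeds voxel size: broad phase incomplete")
    I, J = grid._candidate_pairs()
    if I.size == 0:
        return I, J, np.empty(0)
    d = positions[I] - positions[J]
    dist = np.sqrt(np.einsum("ij,ij->i", d, d))
    keep = dist <= cutoff
    return I[keep], J[keep], dist[keep]


def collect_pairs(state: SimulationState, p: PhysicsParams, cutoff: float | None = None):
    """Voxel-grid pair search over the whole world (compiled fast path).

    Semantically identical to ``candidate_pairs(Grid(p, pos), pos)``: all
    body pairs within ``cutoff`` (default: the voxel size), each once.
    """
    if cutoff is None:
        cutoff = p.voxel_size
    if state.n_bodies == 0:
        e = np.empty(0, dtype=np.int64)
        return e, e.copy(), np.empty(0)
    if _kernels.HAVE_NUMBA:
        _check_inside(state.pos, p)
        dims = max(1, int(np.ceil(p.box_side / p.voxel_size - 1e-12)))
        return _kernels.pairs_within(
            state.pos, state.radius, p.grid_origin, p.voxel_size, dims, cutoff
        )
    grid = Grid(p, state.pos)
    return candidate_pairs(grid, state.pos, cutoff)


# ---------------------------------------------------------------------------
# walls


def wall_distance(pos: np.ndarray, p: PhysicsParams) -> tuple[float, int, np.ndarray]:
    """Distance to the closest of the six boundary planes.

    Returns (distance, wall index, inward unit normal); ties go to the
    first wall in the fixed order floor, ceiling, x-, x+, y-, y+.
    """
    pos = np.asarray(pos, dtype=float)
    dist, wid, nrm = wall_distances(pos[None, :], p)
    return float(dist[0]), int(wid[0]), nrm[0]


def wall_distances(P: np.ndarray, p: PhysicsParams):
    """Vectorized closest-wall query for many positions."""
    _check_inside(P, p)
    L = p.box_side
    d6 = np.stack(
        [P[:, 2] + L, -P[:, 2], P[:, 0], L - P[:, 0], P[:, 1], L - P[:, 1]],
        axis=1,
    )
    wid = np.argmin(d6, axis=1)  # argmin takes the first minimum: fixed tie-break
    dist = d6[np.arange(P.shape[0]), wid]
    return dist, wid, _WALL_NORMALS[wid]


def update_wall_springs(
    state: SimulationState, p: PhysicsParams, a: AdhesionParams, rng: np.random.Generator
) -> None:
    """Stochastic wall attach/detach for every cell (at most one wall spring).

    An unattached cell closer than the adhesion range attaches with
    per-step probability equal to its heritable wall-adhesion trait; the
    anchor is its perpendicular projection on the closest wall, fixed
    thereafter.  An attached spring detaches spontaneously, and always
    when stretched past its maximal length.
    """
    cells = np.flatnonzero(state.cell_mask)
    if cells.size == 0:
        return
    P = state.pos[cells]
    dist, wid, nrm = wall_distances(P, p)
    attached = state.wall_attached[cells]

    # one draw vector per decision kind, fixed order for determinism
    detach_draw = rng.random(cells.size)
    attach_draw = rng.random(cells.size)

    if attached.any():
        ai = cells[attached]
        stretch = np.linalg.norm(state.wall_anchor[ai] - state.pos[ai], axis=1)
        spontaneous = detach_draw[attached] < a.p_detach_wall
        overlong = stretch > a.Lmax_wall
        drop = spontaneous | overlong
        if drop.any():
            di = ai[drop]
            state.wall_attached[di] = False
            state.wall_id[di] = -1
            for bid in state.ids[di].tolist():
                state.record_event("wall_detach", body=bid)

    can_attach = (~attached) & (dist < a.r_adh)
    will = can_attach & (attach_draw < state.wall_adh[cells])
    if will.any():
        wi = cells[will]
        anchors = P[will] - dist[will, None] * nrm[will]
        state.wall_attached[wi] = True
        state.wall_anchor[wi] = anchors
        state.wall_id[wi] = wid[will]
        for bid, w in zip(state.ids[wi].tolist(), wid[will].tolist()):
            state.record_event("wall_attach", body=bid, wall=WALL_NAMES[w])


def wall_spring_force(cell_pos: np.ndarray, anchor: np.ndarray | None, a: AdhesionParams) -> np.ndarray:
    """Hookean restoring force toward the wall anchor; zero without a spring."""
    if anchor is None:
        return np.zeros(3)
    d = np.asarray(anchor, dtype=float) - np.asarray(cell_pos, dtype=float)
    length = float(np.linalg.norm(d))
    if length == 0.0:
        return np.zeros(3)
    return a.k_wall * (length - a.L0_wall) * (d / length)


def _wall_spring_forces(state: SimulationState, a: AdhesionParams) -> np.ndarray:
    F = np.zeros_like(state.pos)
    idx = np.flatnonzero(state.wall_attached)
    if idx.size:
        d = state.wall_anchor[idx] - state.pos[idx]
        length = np.linalg.norm(d, axis=1)
        safe = np.maximum(length, 1e-300)
        F[idx] = (a.k_wall * (length - a.L0_wall) / safe)[:, None] * d
    return F


def update_cell_springs(
    state: SimulationState,
    cell_pairs: tuple[np.ndarray, np.ndarray, np.ndarray],
    a: AdhesionParams,
    rng: np.random.Generator,
) -> None:
    """Stochastic cell-cell spring formation and breakage.

    Unlinked cell pairs closer than the attachment range link with
    probability A_c(i) * A_c(j) (the product of the two heritable
    cell-adhesion traits); existing springs break spontaneously and
    always when stretched past the maximal length.  No pair ever holds
    two springs.
    """
    springs = state.springs
    if len(springs):
        ia = state.index_of(springs.a)
        ib = state.index_of(springs.b)
        length = np.linalg.norm(state.pos[ia] - state.pos[ib], axis=1)
        brk = (rng.random(len(springs)) < a.p_detach_cell) | (length > a.Lmax_cell)
        if brk.any():
            for x, y in zip(springs.a[brk].tolist(), springs.b[brk].tolist()):
                state.record_event("spring_break", a=x, b=y)
            springs.remove_mask(brk)

    I, J, dist = cell_pairs
    close = dist < a.r_attach_cell
    if close.any():
        I, J = I[close], J[close]
        prob = state.cell_adh[I] * state.cell_adh[J]
        form = rng.random(I.size) < prob
        if form.any():
            a_ids = state.ids[I[form]]
            b_ids = state.ids[J[form]]
            before = len(springs)
            springs.add_pairs(a_ids, b_ids)
            if state.log_events and len(springs) > before:
                new_a = springs.a[before:]
                new_b = springs.b[before:]
                for x, y in zip(new_a.tolist(), new_b.tolist()):
                    state.record_event("spring_attach", a=x, b=y)


def cell_spring_force(
    state: SimulationState, body_id: int, a: AdhesionParams
) -> np.ndarray:
    """Net cell-cell spring force on one cell (sum over its active springs)."""
    F = _cell_spring_forces(state, a)
    return F[int(state.index_of(np.array([body_id]))[0])]


def _cell_spring_forces(state: SimulationState, a: AdhesionParams) -> np.ndarray:
    F = np.zeros_like(state.pos)
    springs = state.springs
    if len(springs) == 0:
        return F
    ia = state.index_of(springs.a)
    ib = state.index_of(springs.b)
    d = state.pos[ia] - state.pos[ib]
    length = np.linalg.norm(d, axis=1)
    safe = np.maximum(length, 1e-300)
    f_on_a = (-a.k_cell * (length - a.L0_cell) / safe)[:, None] * d
    np.add.at(F, ia, f_on_a)
    np.add.at(F, ib, -f_on_a)
    return F


# ---------------------------------------------------------------------------
# wall bounce


def resolve_wall_bounce(b: Body, p: PhysicsParams) -> Body:
    """Push an interpenetrating body back inside and attenuate its velocity.

    In the default "full" mode the whole velocity vector is reversed and
    scaled by the restitution factor; in "normal" mode only the normal
    component is reflected.  The reversal applies only when the body is
    moving into the wall, the positional shift always.
    """
    pos = b.position.copy()
    vel = b.velocity.copy()
    pos, vel = _bounce_arrays(pos[None, :], vel[None, :], np.array([b.radius]), p)
    return Body(b.id, b.kind, pos[0], vel[0], b.mass, b.radius)


def _bounce_arrays(pos: np.ndarray, vel: np.ndarray, radius: np.ndarray, p: PhysicsParams):
    L = p.box_side
    planes = (  # (axis, wall coordinate, inward direction)
        (2, -L, 1.0),  # floor
        (2, 0.0, -1.0),  # ceiling
        (0, 0.0, 1.0),
        (0, L, -1.0),
        (1, 0.0, 1.0),
        (1, L, -1.0),
    )
    for axis, coord, sign in planes:
        s = sign * (pos[:, axis] - coord)  # inward distance of center
        pen = radius - s
        hit = pen > 0
        if not hit.any():
            continue
        pos[hit, axis] += sign * pen[hit]
        into = vel[:, axis] * sign < 0
        flip = hit & into
        if not flip.any():
            continue
        if p.bounce_mode == "full":
            vel[flip] *= -p.restitution
        else:
            vel[flip, axis] *= -p.restitution
    return pos, vel


# ---------------------------------------------------------------------------
# totals and the step


def compute_forces(
    state: SimulationState,
    p: PhysicsParams,
    a: AdhesionParams,
    env_vec: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray, np.ndarray],
):
    """Accumulate all forces; returns (F_total, F_internal_sum).

    F_internal_sum is the vector sum over all bodies of the internal
    contributions (contact + cell-cell springs), which must vanish by
    Newton's third law; it is exposed for conservation diagnostics.
    """
    n = state.n_bodies
    F = np.zeros((n, 3))
    if n == 0:
        return F, np.zeros(3)
    g = np.asarray(p.g)
    F += env_vec[None, :]
    F += state.mass[:, None] * g[None, :]
    F += -p.gamma * state.vel

    F_int = np.zeros((n, 3))
    I, J, dist = pairs
    if I.size:
        if _kernels.HAVE_NUMBA:
            _kernels.contact_forces(state.pos, state.vel, state.radius, I, J, dist, p, F_int)
        else:
            contact = state.radius[I] + state.radius[J]
            touching = dist < contact
            if touching.any():
                It, Jt = I[touching], J[touching]
                dvec = state.pos[It] - state.pos[Jt]
                vrel = state.vel[It] - state.vel[Jt]
                f = _collision_kernel(dvec, dist[touching], vrel, contact[touching], p)
                np.add.at(F_int, It, f)
                np.add.at(F_int, Jt, -f)
    F_int += _cell_spring_forces(state, a)
    F += F_int
    F += _wall_spring_forces(state, a)
    return F, F_int.sum(axis=0)


def total_cell_force(
    state: SimulationState,
    body_id: int,
    p: PhysicsParams,
    a: AdhesionParams,
    env_vec: np.ndarray | None = None,
) -> np.ndarray:
    """Total force on one cell: environment + gravity + drag + contacts +
    wall spring + cell-cell springs (computed from the current state)."""
    if env_vec is None:
        env_vec = np.zeros(3)
    grid = Grid(p, state.pos)
    pairs = candidate_pairs(grid, state.pos)
    F, _ = compute_forces(state, p, a, env_vec, pairs)
    return F[int(state.index_of(np.array([body_id]))[0])]


def total_particle_force(
    state: SimulationState,
    body_id: int,
    p: PhysicsParams,
    env_vec: np.ndarray | None = None,
) -> np.ndarray:
    """Total force on one particle: as for cells but with no adhesion terms
    ever (particles cannot adhere to walls or to other bodies)."""
    i = int(state.index_of(np.array([body_id]))[0])
    if state.kind[i] != 1:
        raise ValueError(f"body {body_id} is not a particle")
    # particles hold no springs, so the adhesion terms are structurally zero
    return total_cell_force(state, body_id, p, AdhesionParams(), env_vec)


def _resolve_coincident(state: SimulationState, pairs, rng: np.random.Generator):
    """Deterministically jitter one body of any coincident-center pair."""
    I, J, dist = pairs
    bad = dist < 1e-9
    if not bad.any():
        return pairs
    for k in np.flatnonzero(bad):
        j = max(I[k], J[k])  # move the younger body
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        state.pos[j] += 1e-6 * state.radius[j] * direction
        state.record_event("coincident_jitter", body=int(state.ids[j]))
        d = state.pos[I[k]] - state.pos[J[k]]
        dist[k] = np.linalg.norm(d)
    return I, J, dist


def _enforce_spring_legality(state: SimulationState, a: AdhesionParams) -> None:
    """End-of-step guarantee: no spring longer than its maximal length."""
    springs = state.springs
    if len(springs):
        ia = state.index_of(springs.a)
        ib = state.index_of(springs.b)
        length = np.linalg.norm(state.pos[ia] - state.pos[ib], axis=1)
        over = length > a.Lmax_cell
        if over.any():
            for x, y in zip(springs.a[over].tolist(), springs.b[over].tolist()):
                state.record_event("spring_break", a=x, b=y)
            springs.remove_mask(over)
    idx = np.flatnonzero(state.wall_attached)
    if idx.size:
        stretch = np.linalg.norm(state.wall_anchor[idx] - state.pos[idx], axis=1)
        over = stretch > a.Lmax_wall
        if over.any():
            di = idx[over]
            state.wall_attached[di] = False
            state.wall_id[di] = -1
            for bid in state.ids[di].tolist():
                state.record_event("wall_detach", body=bid)


def integrate(state: SimulationState, p: PhysicsParams, a: AdhesionParams) -> None:
    """Advance all bodies one time step dt.

    Fixed in-step order: (1) rebuild the voxel grid and enumerate
    candidate pairs, (2) wall and cell spring attach/detach updates,
    (3) force accumulation with one shared environmental draw,
    (4) semi-implicit Euler velocity-then-position update, (5) wall
    bounce resolution and end-of-step spring legality, (6) containment
    and finiteness checks.
    """
    rng = state.rng.physics
    n = state.n_bodies
    if n == 0:
        return
    pairs = collect_pairs(state, p)
    pairs = _resolve_coincident(state, pairs, rng)

    cmask = state.cell_mask
    I, J, dist = pairs
    both_cells = cmask[I] & cmask[J]
    cell_pairs = (I[both_cells], J[both_cells], dist[both_cells])

    update_wall_springs(state, p, a, rng)
    update_cell_springs(state, cell_pairs, a, rng)

    env_vec = env_force(rng, p.sigma)
    F, internal_sum = compute_forces(state, p, a, env_vec, pairs)
    state.last_diag = {
        "internal_force_sum": internal_sum,
        "internal_force_residual": float(np.abs(internal_sum).max()),
    }

    state.vel += (F / state.mass[:, None]) * p.dt
    state.pos += state.vel * p.dt

    _bounce_arrays(state.pos, state.vel, state.radius, p)
    _enforce_spring_legality(state, a)

    if not (np.isfinite(state.pos).all() and np.isfinite(state.vel).all()):
        bad = ~(np.isfinite(state.pos).all(axis=1) & np.isfinite(state.vel).all(axis=1))
        bid = int(state.ids[np.flatnonzero(bad)[0]])
        raise NumericalInstabilityError(
            f"non-finite state for body {bid} at step {state.step}"
        )
    state.check_containment()
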