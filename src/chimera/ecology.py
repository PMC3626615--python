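"""Nutrient economy: top-face inflow, degradation to waste, grazing.

Every step, ``eta`` nutrient particles enter through the top face, split
uniformly over the nutrient classes.  Nutrients and detritus are removed
memorylessly (per-step Bernoulli) at their respective degradation rates,
detritus strictly slower.  A cell touching a particle consumes it only if
its efficiency on that class is positive, gaining mass linearly in the
particle mass; otherwise the particle is merely deflected by the contact
force.
"""

from __future__ import annotations

import numpy as np

from .config import EcologyParams
from .state import PARTICLE, SimulationState

__all__ = ["inject_nutrients", "degrade_particles", "resolve_feeding", "spawn_detritus"]


def inject_nutrients(state: SimulationState, e: EcologyParams, rng: np.random.Generator) -> None:
    """Append exactly ``eta`` new nutrient particles at the top face.

    Classes are split evenly; any remainder rotates round-robin with the
    step index so no class is favored in the long run.  Initial positions
    are uniform over the top face (just inside), initial velocity zero.
    """
    eta = e.eta
    if eta == 0:
        return
    ns = e.n_sources
    base, rem = divmod(eta, ns)
    counts = np.full(ns, base, dtype=np.int64)
    if rem:
        offset = state.step % ns
        counts[(offset + np.arange(rem)) % ns] += 1
    classes = np.repeat(np.arange(ns), counts)
    L = state.config.physics.box_side
    r = e.particle_radius
    xy = rng.uniform(r, L - r, size=(eta, 2))
    pos = np.column_stack([xy, np.full(eta, -r)])
    state.append(
        kind=np.full(eta, PARTICLE, dtype=np.int8),
        pos=pos,
        vel=np.zeros((eta, 3)),
        mass=np.full(eta, e.particle_mass),
        radius=np.full(eta, r),
        pclass=classes.astype(np.int16),
        eff=np.zeros((eta, state.n_classes)),
        wall_adh=np.zeros(eta),
        cell_adh=np.zeros(eta),
        wall_attached=np.zeros(eta, dtype=bool),
        wall_anchor=np.zeros((eta, 3)),
        wall_id=np.full(eta, -1, dtype=np.int8),
    )
    state.counters.injected += eta
    np.add.at(state.counters.injected_by_class, classes, 1)


def spawn_detritus(
    state: SimulationState, centers: np.ndarray, radii: np.ndarray, rng: np.random.Generator
) -> None:
    """Release detritus particles uniformly inside dead cells' volumes."""
    e = state.config.ecology
    n_det = state.config.evolution.n_detritus
    if n_det == 0 or centers.shape[0] == 0:
        return
    k = centers.shape[0] * n_det
    base = np.repeat(centers, n_det, axis=0)
    spread = np.repeat(radii, n_det)
    direction = rng.normal(size=(k, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    rad = spread * rng.uniform(0.0, 1.0, size=k) ** (1.0 / 3.0)
    pos = base + rad[:, None] * direction
    L = state.config.physics.box_side
    pr = e.detritus_radius if e.detritus_radius is not None else e.particle_radius
    pm = e.detritus_mass if e.detritus_mass is not None else e.particle_mass
    pos[:, 0] = np.clip(pos[:, 0], pr, L - pr)
    pos[:, 1] = np.clip(pos[:, 1], pr, L - pr)
    pos[:, 2] = np.clip(pos[:, 2], -L + pr, -pr)
    state.append(
        kind=np.full(k, PARTICLE, dtype=np.int8),
        pos=pos,
        vel=np.zeros((k, 3)),
        mass=np.full(k, pm),
        radius=np.full(k, pr),
        pclass=np.full(k, e.detritus_class, dtype=np.int16),
        eff=np.zeros((k, state.n_classes)),
        wall_adh=np.zeros(k),
        cell_adh=np.zeros(k),
        wall_attached=np.zeros(k, dtype=bool),
        wall_anchor=np.zeros((k, 3)),
        wall_id=np.full(k, -1, dtype=np.int8),
    )
    state.counters.detritus_spawned += k


def degrade_particles(state: SimulationState, e: EcologyParams, rng: np.random.Generator) -> None:
    """Memoryless removal: nutrients at rate delta, detritus at delta_detritus."""
    pmask = state.particle_mask
    idx = np.flatnonzero(pmask)
    if idx.size == 0:
        return
    is_det = state.pclass[idx] == e.detritus_class
    rate = np.where(is_det, e.delta_detritus, e.delta)
    gone = rng.random(idx.size) < rate
    if not gone.any():
        return
    removed = idx[gone]
    n_det = int(is_det[gone].sum())
    state.counters.degraded_detritus += n_det
    state.counters.degraded_nutrients += int(gone.sum()) - n_det
    state.remove_indices(removed)


def resolve_feeding(
    state: SimulationState, pairs: tuple[np.ndarray, np.ndarray, np.ndarray]
) -> None:
    """Consume particles in contact with cells able to metabolise them.

    A particle of class k in contact with a cell whose efficiency e_k is
    positive is removed and the cell gains e_k times the particle mass.
    When several eligible cells touch one particle, the nearest center
    wins (ties to the lowest cell id).  Cells with zero efficiency on the
    class deflect the particle instead (contact physics only).
    """
    I, J, dist = pairs
    if I.size == 0:
        return
    cmask = state.cell_mask
    # orient pairs as (cell, particle)
    cp = cmask[I] & ~cmask[J]
    pc = cmask[J] & ~cmask[I]
    cell_idx = np.concatenate([I[cp], J[pc]])
    part_idx = np.concatenate([J[cp], I[pc]])
    d = np.concatenate([dist[cp], dist[pc]])
    if cell_idx.size == 0:
        return
    touching = d < state.radius[cell_idx] + state.radius[part_idx]
    cell_idx, part_idx, d = cell_idx[touching], part_idx[touching], d[touching]
    if cell_idx.size == 0:
        return
    klass = state.pclass[part_idx]
    eff = state.eff[cell_idx, klass]
    able = eff > 0
    cell_idx, part_idx, d, klass, eff = (
        cell_idx[able], part_idx[able], d[able], klass[able], eff[able],
    )
    if cell_idx.size == 0:
        return
    # nearest-center cell wins each particle; deterministic tie-break by cell id
    order = np.lexsort((state.ids[cell_idx], d, part_idx))
    part_sorted = part_idx[order]
    first = np.ones(order.size, dtype=bool)
    first[1:] = part_sorted[1:] != part_sorted[:-1]
    win = order[first]
    wc, wp = cell_idx[win], part_idx[win]
    gain = eff[win] * state.mass[wp]
    np.add.at(state.mass, wc, gain)
    state.counters.mass_consumed += float(gain.sum())
    np.add.at(state.counters.consumed_by_class, klass[win], 1)
    if state.log_events:
        for c, pi, k in zip(state.ids[wc].tolist(), state.ids[wp].tolist(), klass[win].tolist()):
            state.record_event("feeding", cell=c, particle=pi, klass=int(k))
    state.remove_indices(wp)
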