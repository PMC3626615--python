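"""Cell life cycle: maintenance, death into detritus, division, mutation.

The heritable genome of a cell is its efficiency vector over the nutrient
classes plus detritus (non-negative, summing to one) and its two adhesion
traits (wall and cell-cell, each in [0, 1]).  Offspring inherit a
mutated copy: each entry is perturbed by zero-mean Gaussian noise with
probability ``p_mut``, clipped to [0, 1], and the efficiencies are then
L1-renormalized so the sum-to-one constraint holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import EvoParams
from .ecology import spawn_detritus
from .state import CELL, SimulationState

__all__ = ["Genome", "mutate_offspring", "apply_maintenance", "process_death", "attempt_divisions"]


@dataclass
class Genome:
    efficiencies: np.ndarray
    wall_adhesion: float
    cell_adhesion: float

    def validate(self) -> None:
        e = self.efficiencies
        if (e < 0).any() or (e > 1).any():
            raise ValueError("efficiencies must lie in [0, 1]")
        if e.sum() != 1.0:
            raise ValueError("efficiencies must sum to one exactly")
        for t in (self.wall_adhesion, self.cell_adhesion):
            if not 0.0 <= t <= 1.0:
                raise ValueError("adhesion traits must lie in [0, 1]")


_EFF_SCALE = 1 << 30  # efficiencies live on a 2^-30 grid


def _renormalize(e: np.ndarray) -> np.ndarray:
    """L1-normalize so the sum equals 1.0 *exactly*.

    Floating-point division alone leaves a residual of a few ulp that no
    finite sequence of corrections reliably removes, so the normalized
    vector is snapped to a 2^-30 grid: grid multiples and their partial
    sums are all exact in double precision, making the unit-sum
    constraint hold identically.  The quantization (< 1e-9 per entry) is
    far below the mutation scale.
    """
    e = e / e.sum()
    q = np.rint(e * _EFF_SCALE).astype(np.int64)
    q[int(np.argmax(q))] += _EFF_SCALE - q.sum()  # |correction| <= len(e)/2
    return q.astype(np.float64) / _EFF_SCALE


def mutate_offspring(g: Genome, p: EvoParams, rng: np.random.Generator) -> Genome:
    """Return a freshly mutated copy of a parent genome (parent untouched).

    If clipping ever zeroes the whole efficiency vector the perturbation
    is redrawn, so normalization never divides by zero.
    """
    eff = g.efficiencies.copy()
    for _ in range(100):
        trial = eff.copy()
        mask = rng.random(trial.size) < p.p_mut
        if mask.any():
            trial[mask] += rng.normal(0.0, p.sigma_mut, size=int(mask.sum()))
        np.clip(trial, 0.0, 1.0, out=trial)
        if trial.sum() > 0:
            eff = _renormalize(trial)
            break
    else:  # pragma: no cover - requires an all-zero parent, which is illegal
        raise RuntimeError("mutation repeatedly produced an all-zero efficiency vector")
    wall = g.wall_adhesion
    if rng.random() < p.p_mut:
        wall += rng.normal(0.0, p.sigma_mut)
    cell = g.cell_adhesion
    if rng.random() < p.p_mut:
        cell += rng.normal(0.0, p.sigma_mut)
    return Genome(eff, float(np.clip(wall, 0.0, 1.0)), float(np.clip(cell, 0.0, 1.0)))


def apply_maintenance(state: SimulationState, p: EvoParams) -> None:
    """Constant per-step energy drain on every cell (mass units)."""
    cmask = state.cell_mask
    state.mass[cmask] -= p.maintenance_cost
    state.counters.mass_maintenance += p.maintenance_cost * float(cmask.sum())


def process_death(state: SimulationState, p: EvoParams, rng: np.random.Generator) -> None:
    """Remove starved cells and disintegrate them into detritus particles.

    Every cell whose mass fell below the critical threshold is removed;
    its adhesion springs are destroyed and ``n_detritus`` detritus
    particles are released uniformly within its former volume.
    """
    dead = np.flatnonzero(state.cell_mask & (state.mass < p.m_min))
    if dead.size == 0:
        return
    dead_ids = state.ids[dead]
    centers = state.pos[dead].copy()
    radii = state.radius[dead].copy()
    state.springs.drop_ids(dead_ids)
    if state.log_events:
        for bid in dead_ids.tolist():
            state.record_event("death", cell=bid)
    state.counters.deaths += dead.size
    state.counters.mass_death += float(state.mass[dead].sum())
    state.remove_indices(dead)
    spawn_detritus(state, centers, radii, rng)


def attempt_divisions(
    state: SimulationState,
    p: EvoParams,
    neighbor_counts: np.ndarray,
    rng_mut: np.random.Generator,
    rng_place: np.random.Generator,
) -> None:
    """Divide every eligible cell: mass at least 2 m0 and local density
    below the threshold (fewer than rho_max cells within r_neighborhood).

    The daughter starts at the canonical birth mass m0 (transferred from
    the mother) with a mutated genome, placed at a random offset of at
    most two radii from the mother and clamped inside the box.  With
    ``half_split`` the mass is divided evenly instead.

    ``neighbor_counts`` is the per-body count of other cells within the
    division neighborhood, evaluated once at the start of the stage.
    """
    cmask = state.cell_mask
    ready = np.flatnonzero(cmask & (state.mass >= 2.0 * p.m0) & (neighbor_counts < p.rho_max))
    if ready.size == 0:
        return
    L = state.config.physics.box_side
    new_rows = []
    for i in ready.tolist():
        mother = Genome(state.eff[i].copy(), float(state.wall_adh[i]), float(state.cell_adh[i]))
        child = mutate_offspring(mother, p, rng_mut)
        if p.half_split:
            m_child = state.mass[i] / 2.0
            state.mass[i] -= m_child
        else:
            m_child = p.m0
            state.mass[i] -= p.m0
        r = state.radius[i]
        direction = rng_place.normal(size=3)
        direction /= np.linalg.norm(direction)
        offset = rng_place.uniform(1.0, 2.0) * r * direction
        pos = state.pos[i] + offset
        pos[0] = np.clip(pos[0], r, L - r)
        pos[1] = np.clip(pos[1], r, L - r)
        pos[2] = np.clip(pos[2], -L + r, -r)
        new_rows.append((i, pos, m_child, r, child))
    n = len(new_rows)
    eff_new = np.stack([row[4].efficiencies for row in new_rows])
    ids = state.append(
        kind=np.full(n, CELL, dtype=np.int8),
        pos=np.stack([row[1] for row in new_rows]),
        vel=state.vel[[row[0] for row in new_rows]].copy(),
        mass=np.array([row[2] for row in new_rows]),
        radius=np.array([row[3] for row in new_rows]),
        pclass=np.full(n, -1, dtype=np.int16),
        eff=eff_new,
        wall_adh=np.array([row[4].wall_adhesion for row in new_rows]),
        cell_adh=np.array([row[4].cell_adhesion for row in new_rows]),
        wall_attached=np.zeros(n, dtype=bool),
        wall_anchor=np.zeros((n, 3)),
        wall_id=np.full(n, -1, dtype=np.int8),
    )
    state.counters.births += n
    if state.log_events:
        for (i, _, _, _, child), cid in zip(new_rows, ids.tolist()):
            state.record_event(
                "birth",
                parent=int(state.ids[i]),
                child=cid,
                efficiencies=[float(x) for x in child.efficiencies],
                wall_adhesion=child.wall_adhesion,
                cell_adhesion=child.cell_adhesion,
            )
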