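"""The per-step composition of physics, ecology and evolution.

Fixed stage order within a step: inject -> physics step -> feeding ->
degradation -> maintenance -> death -> division -> metrics.  A run is
fully reproducible from (config, seed): every stochastic stage draws
from its own named substream in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import RunConfig
from .ecology import degrade_particles, inject_nutrients, resolve_feeding
from .evolution import apply_maintenance, attempt_divisions, process_death
from .metrics import StepRecord, classify_phase, population_summary
from .physics import collect_pairs, integrate
from .state import SimulationState, init_state

__all__ = ["RunResult", "run_simulation", "step_once"]


@dataclass
class RunResult:
    records: list[StepRecord]
    final_state: SimulationState
    events: list[dict]
    config: RunConfig
    seed: int

    @property
    def label(self) -> str:
        return classify_phase(self.records, self.config)


def _neighbor_counts(state: SimulationState, pairs, r_neighborhood: float):
    """Per-body count of *other cells* within the division neighborhood,
    keyed by body id (robust to later removals)."""
    I, J, dist = pairs
    counts = np.zeros(state.n_bodies, dtype=np.int64)
    if I.size:
        cmask = state.cell_mask
        sel = cmask[I] & cmask[J] & (dist < r_neighborhood)
        np.add.at(counts, I[sel], 1)
        np.add.at(counts, J[sel], 1)
    return state.ids.copy(), counts


def step_once(state: SimulationState) -> None:
    """Advance the full model one step (physics + ecology + evolution)."""
    cfg = state.config
    inject_nutrients(state, cfg.ecology, state.rng.ecology)
    integrate(state, cfg.physics, cfg.adhesion)

    pairs = collect_pairs(state, cfg.physics)
    snap_ids, snap_counts = _neighbor_counts(state, pairs, cfg.evolution.r_neighborhood)

    resolve_feeding(state, pairs)
    degrade_particles(state, cfg.ecology, state.rng.ecology)
    apply_maintenance(state, cfg.evolution)
    process_death(state, cfg.evolution, state.rng.placement)

    # map the pre-removal neighbor counts onto the surviving bodies
    idx = np.searchsorted(snap_ids, state.ids)
    idx = np.minimum(idx, max(snap_ids.size - 1, 0))
    if snap_ids.size:
        counts_now = np.where(snap_ids[idx] == state.ids, snap_counts[idx], 0)
    else:
        counts_now = np.zeros(state.n_bodies, dtype=np.int64)
    attempt_divisions(state, cfg.evolution, counts_now, state.rng.mutation, state.rng.placement)
    state.step += 1


def run_simulation(config: RunConfig, seed: int | None = None) -> RunResult:
    """Run a seeded simulation and collect the recorded time series.

    Extinction is not an error: the world keeps running with particles
    only.  ``steps == 0`` yields just the initial record.
    """
    config.validate()
    if seed is None:
        seed = config.run.seed
    state = init_state(config, seed)
    records = [population_summary(state)]
    interval = config.run.record_interval
    for _ in range(config.run.steps):
        step_once(state)
        if state.step % interval == 0:
            records.append(population_summary(state))
    if state.step % interval != 0:
        records.append(population_summary(state))
    return RunResult(records=records, final_state=state, events=state.events, config=config, seed=int(seed))
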