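"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chimera.config import default_config
from chimera.state import CELL, PARTICLE, SimulationState

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def cfg():
    return default_config()


@pytest.fixture
def quiet_cfg():
    """Default config with event logging off (fast paths)."""
    return default_config().replace(run={"log_events": False})


def brute_force_pairs(positions: np.ndarray, cutoff: float) -> set[tuple[int, int]]:
    """O(n^2) all-pairs oracle: every (i, j), i < j, with distance <= cutoff."""
    n = positions.shape[0]
    out = set()
    for i in range(n):
        d = positions[i + 1 :] - positions[i]
        dist = np.sqrt((d * d).sum(axis=1))
        for j in np.flatnonzero(dist <= cutoff):
            out.add((i, int(i + 1 + j)))
    return out


def random_world(cfg, seed: int, n_cells: int = 30, n_particles: int = 60) -> SimulationState:
    """A populated world with bodies scattered uniformly inside the box."""
    rng = np.random.default_rng(seed)
    state = SimulationState(cfg, seed)
    L = cfg.physics.box_side
    rc, rp = cfg.evolution.cell_radius, cfg.ecology.particle_radius

    def positions(n, r):
        xy = rng.uniform(r, L - r, size=(n, 2))
        z = rng.uniform(-L + r, -r, size=n)
        return np.column_stack([xy, z])

    eff = np.zeros((n_cells, cfg.ecology.n_classes))
    eff[:, 0] = 1.0
    state.append(
        kind=np.full(n_cells, CELL, dtype=np.int8),
        pos=positions(n_cells, rc),
        vel=rng.normal(0, 0.05, size=(n_cells, 3)),
        mass=np.full(n_cells, cfg.evolution.m0),
        radius=np.full(n_cells, rc),
        pclass=np.full(n_cells, -1, dtype=np.int16),
        eff=eff,
        wall_adh=rng.uniform(0, 1, n_cells),
        cell_adh=rng.uniform(0, 1, n_cells),
        wall_attached=np.zeros(n_cells, dtype=bool),
        wall_anchor=np.zeros((n_cells, 3)),
        wall_id=np.full(n_cells, -1, dtype=np.int8),
    )
    if n_particles:
        state.append(
            kind=np.full(n_particles, PARTICLE, dtype=np.int8),
            pos=positions(n_particles, rp),
            vel=rng.normal(0, 0.05, size=(n_particles, 3)),
            mass=np.full(n_particles, cfg.ecology.particle_mass),
            radius=np.full(n_particles, rp),
            pclass=rng.integers(0, cfg.ecology.n_sources, n_particles).astype(np.int16),
            eff=np.zeros((n_particles, cfg.ecology.n_classes)),
            wall_adh=np.zeros(n_particles),
            cell_adh=np.zeros(n_particles),
            wall_attached=np.zeros(n_particles, dtype=bool),
            wall_anchor=np.zeros((n_particles, 3)),
            wall_id=np.full(n_particles, -1, dtype=np.int8),
        )
    return state
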