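import numpy as np
import pytest

from chimera.config import default_config
from chimera.ecology import degrade_particles, inject_nutrients, resolve_feeding
from chimera.simulation import run_simulation, step_once
from chimera.state import CELL, PARTICLE, SimulationState, init_state


class TestInjection:
    def test_zero_inflow_adds_nothing(self, cfg):
        state = SimulationState(cfg, 0)
        e = cfg.replace(ecology={"eta": 0}).ecology
        inject_nutrients(state, e, state.rng.ecology)
        assert state.n_bodies == 0

    def test_even_split_over_classes(self, cfg):
        e = cfg.replace(ecology={"eta": 6, "n_sources": 3}).ecology
        state = SimulationState(cfg.replace(ecology={"eta": 6, "n_sources": 3}), 0)
        inject_nutrients(state, e, state.rng.ecology)
        counts = np.bincount(state.pclass, minlength=3)
        assert counts[:3].tolist() == [2, 2, 2]

    def test_particles_start_at_top_with_zero_velocity(self, cfg):
        state = SimulationState(cfg, 0)
        inject_nutrients(state, cfg.ecology, state.rng.ecology)
        assert (state.pos[:, 2] == -cfg.ecology.particle_radius).all()
        assert (state.vel == 0).all()

    def test_cumulative_injection_counter(self, quiet_cfg):
        cfg = quiet_cfg.replace(ecology={"eta": 4}, evolution={"n_founders": 0})
        state = init_state(cfg, 0)
        for _ in range(250):
            step_once(state)
        assert state.counters.injected == 1000


class TestDegradation:
    def _particles_only(self, cfg, n, detritus=False):
        state = SimulationState(cfg, 0)
        klass = cfg.ecology.detritus_class if detritus else 0
        state.append(
            kind=np.full(n, PARTICLE, dtype=np.int8),
            pos=np.tile([0.5, 0.5, -0.5], (n, 1)),
            vel=np.zeros((n, 3)),
            mass=np.full(n, cfg.ecology.particle_mass),
            radius=np.full(n, cfg.ecology.particle_radius),
            pclass=np.full(n, klass, dtype=np.int16),
            eff=np.zeros((n, cfg.ecology.n_classes)),
            wall_adh=np.zeros(n),
            cell_adh=np.zeros(n),
            wall_attached=np.zeros(n, dtype=bool),
            wall_anchor=np.zeros((n, 3)),
            wall_id=np.full(n, -1, dtype=np.int8),
        )
        return state

    def test_certain_removal(self, cfg):
        e = cfg.replace(ecology={"delta": 0.999999, "delta_detritus": 0.0001}).ecology
        state = self._particles_only(cfg, 50)
        rng = np.random.default_rng(0)
        # delta ~ 1: everything goes in one step (probability astronomically close)
        degrade_particles(state, e, rng)
        assert state.n_bodies <= 1

    def test_binomial_removal_count(self, cfg):
        e = cfg.replace(ecology={"delta": 0.1, "delta_detritus": 0.01}).ecology
        state = self._particles_only(cfg, 10_000)
        rng = np.random.default_rng(1)
        degrade_particles(state, e, rng)
        removed = 10_000 - state.n_bodies
        tol = 3 * np.sqrt(10_000 * 0.1 * 0.9)
        assert abs(removed - 1000) < tol

    def test_detritus_outlives_nutrients_on_average(self, cfg):
        # memoryless lifetimes: 1/delta_detritus > 1/delta by construction
        assert 1.0 / cfg.ecology.delta_detritus > 1.0 / cfg.ecology.delta


def world_with_cell_and_particle(cfg, efficiency_vector, klass=0, touching=True):
    state = SimulationState(cfg, 0)
    rc, rp = cfg.evolution.cell_radius, cfg.ecology.particle_radius
    gap = (rc + rp) * (0.9 if touching else 1.1)
    eff = np.zeros((1, cfg.ecology.n_classes))
    eff[0, : len(efficiency_vector)] = efficiency_vector
    state.append(
        kind=np.array([CELL], dtype=np.int8),
        pos=np.array([[0.5, 0.5, -0.5]]),
        vel=np.zeros((1, 3)),
        mass=np.array([1.0]),
        radius=np.array([rc]),
        pclass=np.array([-1], dtype=np.int16),
        eff=eff,
        wall_adh=np.zeros(1),
        cell_adh=np.zeros(1),
        wall_attached=np.zeros(1, dtype=bool),
        wall_anchor=np.zeros((1, 3)),
        wall_id=np.full(1, -1, dtype=np.int8),
    )
    state.append(
        kind=np.array([PARTICLE], dtype=np.int8),
        pos=np.array([[0.5 + gap, 0.5, -0.5]]),
        vel=np.zeros((1, 3)),
        mass=np.array([cfg.ecology.particle_mass]),
        radius=np.array([rp]),
        pclass=np.array([klass], dtype=np.int16),
        eff=np.zeros((1, cfg.ecology.n_classes)),
        wall_adh=np.zeros(1),
        cell_adh=np.zeros(1),
        wall_attached=np.zeros(1, dtype=bool),
        wall_anchor=np.zeros((1, 3)),
        wall_id=np.full(1, -1, dtype=np.int8),
    )
    return state


def contact_pairs(state, cfg):
    from chimera.physics import collect_pairs

    return collect_pairs(state, cfg.physics)


class TestFeeding:
    def test_zero_efficiency_deflects(self, cfg):
        state = world_with_cell_and_particle(cfg, [0.0, 1.0], klass=0)
        resolve_feeding(state, contact_pairs(state, cfg))
        assert state.n_bodies == 2  # particle persists
        assert state.mass[0] == 1.0

    def test_full_efficiency_consumes_particle(self, cfg):
        state = world_with_cell_and_particle(cfg, [1.0], klass=0)
        mp = cfg.ecology.particle_mass
        resolve_feeding(state, contact_pairs(state, cfg))
        assert state.n_cells == 1 and state.n_bodies == 1
        assert state.mass[0] == pytest.approx(1.0 + mp)

    def test_linear_intake_rule(self, cfg):
        # e = 0.5 on the contacted class: gain is half the particle mass
        state = world_with_cell_and_particle(cfg, [0.5, 0.5], klass=0)
        mp = cfg.ecology.particle_mass
        resolve_feeding(state, contact_pairs(state, cfg))
        assert state.mass[0] == pytest.approx(1.0 + 0.5 * mp)

    def test_out_of_contact_particle_untouched(self, cfg):
        state = world_with_cell_and_particle(cfg, [1.0], touching=False)
        resolve_feeding(state, contact_pairs(state, cfg))
        assert state.n_bodies == 2

    def test_nearest_cell_wins_conflict(self, cfg):
        state = world_with_cell_and_particle(cfg, [1.0], klass=0)
        rc = cfg.evolution.cell_radius
        # second, nearer eligible cell
        eff = np.zeros((1, cfg.ecology.n_classes))
        eff[0, 0] = 1.0
        px = state.pos[1, 0]
        state.append(
            kind=np.array([CELL], dtype=np.int8),
            pos=np.array([[px + 0.5 * rc, 0.5, -0.5]]),
            vel=np.zeros((1, 3)),
            mass=np.array([1.0]),
            radius=np.array([rc]),
            pclass=np.array([-1], dtype=np.int16),
            eff=eff,
            wall_adh=np.zeros(1),
            cell_adh=np.zeros(1),
            wall_attached=np.zeros(1, dtype=bool),
            wall_anchor=np.zeros((1, 3)),
            wall_id=np.full(1, -1, dtype=np.int8),
        )
        resolve_feeding(state, contact_pairs(state, cfg))
        assert state.mass[state.ids == 2][0] > 1.0  # the nearer cell fed
        assert state.mass[state.ids == 0][0] == 1.0


class TestBookkeeping:
    def test_particle_budget_closes_every_run(self, quiet_cfg):
        cfg = quiet_cfg.replace(run={"steps": 400})
        res = run_simulation(cfg, 21)
        st = res.final_state
        c = st.counters
        e = cfg.ecology
        nutrients_present = int(((st.pclass >= 0) & (st.pclass < e.n_sources)).sum())
        consumed_nutrients = int(c.consumed_by_class[: e.n_sources].sum())
        assert c.injected == consumed_nutrients + c.degraded_nutrients + nutrients_present
        det_present = int((st.pclass == e.detritus_class).sum())
        assert c.detritus_spawned == (
            int(c.consumed_by_class[e.detritus_class]) + c.degraded_detritus + det_present
        )

    def test_cell_mass_budget_closes(self, quiet_cfg):
        cfg = quiet_cfg.replace(run={"steps": 400})
        res = run_simulation(cfg, 22)
        st = res.final_state
        c = st.counters
        total = float(st.mass[st.cell_mask].sum())
        init = cfg.evolution.n_founders * cfg.evolution.m0
        expected = init + c.mass_consumed - c.mass_maintenance - c.mass_death
        assert total == pytest.approx(expected, abs=1e-9)
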