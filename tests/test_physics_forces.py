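import numpy as np
import pytest

from chimera.config import default_config
from chimera.physics import (
    cell_spring_force,
    compute_forces,
    collect_pairs,
    drag_force,
    env_force,
    pair_collision_force,
    total_cell_force,
    wall_spring_force,
)
from chimera.state import Body, SimulationState, CELL

from conftest import random_world


def make_body(bid, pos, vel=(0, 0, 0), mass=1.0, radius=0.07, kind=CELL):
    return Body(bid, kind, np.asarray(pos, float), np.asarray(vel, float), mass, radius)


class TestEnvForce:
    def test_zero_strength_field(self):
        rng = np.random.default_rng(0)
        assert np.array_equal(env_force(rng, 0.0), np.zeros(3))

    def test_components_bounded_by_sigma(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            f = env_force(rng, 2.0)
            assert (np.abs(f) <= 2.0).all()

    def test_monte_carlo_mean_vanishes(self):
        # mean of 1e4 uniform[-1,1] draws: |mean| < 3 * (1/sqrt(3)) / 100
        rng = np.random.default_rng(2)
        draws = np.array([env_force(rng, 1.0) for _ in range(10_000)])
        tol = 3.0 * (1.0 / np.sqrt(3.0)) / 100.0
        assert (np.abs(draws.mean(axis=0)) < tol).all()

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            env_force(np.random.default_rng(0), -1.0)


class TestDragForce:
    def test_rest_and_linear_form(self):
        assert np.array_equal(drag_force(np.zeros(3), 1.0), np.zeros(3))
        np.testing.assert_allclose(drag_force(np.array([1.0, 0, 0]), 0.5), [-0.5, 0, 0])

    def test_free_body_speed_decays_geometrically(self):
        # explicit velocity update: v' = v (1 - gamma dt / m) each step
        cfg = default_config().replace(
            physics={"sigma": 0.0, "g": (0.0, 0.0, 0.0)},
            run={"log_events": False},
        )
        state = _single_cell(cfg, pos=(0.5, 0.5, -0.5), vel=(0.02, 0.0, 0.0))
        p = cfg.physics
        ratio = 1.0 - p.gamma * p.dt / state.mass[0]
        v0 = state.vel[0, 0]
        from chimera.physics import integrate

        for n in range(1, 6):
            integrate(state, p, cfg.adhesion)
            np.testing.assert_allclose(state.vel[0, 0], v0 * ratio**n, rtol=1e-12)


def _single_cell(cfg, pos, vel=(0, 0, 0), wall_adh=0.0):
    state = SimulationState(cfg, 0)
    state.append(
        kind=np.array([CELL], dtype=np.int8),
        pos=np.array([pos], dtype=float),
        vel=np.array([vel], dtype=float),
        mass=np.array([cfg.evolution.m0]),
        radius=np.array([cfg.evolution.cell_radius]),
        pclass=np.array([-1], dtype=np.int16),
        eff=np.eye(1, cfg.ecology.n_classes),
        wall_adh=np.array([wall_adh]),
        cell_adh=np.array([0.0]),
        wall_attached=np.array([False]),
        wall_anchor=np.zeros((1, 3)),
        wall_id=np.array([-1], dtype=np.int8),
    )
    return state


class TestPairCollision:
    def test_no_interpenetration_no_force(self, cfg):
        a = make_body(0, (0.3, 0.3, -0.5))
        b = make_body(1, (0.3 + 0.14 + 0.1, 0.3, -0.5))
        assert np.array_equal(pair_collision_force(a, b, cfg.physics), np.zeros(3))

    def test_newtons_third_law(self, cfg):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pa = np.array([0.5, 0.5, -0.5])
            pb = pa + rng.normal(0, 0.04, 3)
            a = make_body(0, pa, rng.normal(0, 0.1, 3))
            b = make_body(1, pb, rng.normal(0, 0.1, 3))
            fab = pair_collision_force(a, b, cfg.physics)
            fba = pair_collision_force(b, a, cfg.physics)
            np.testing.assert_allclose(fab, -fba, atol=1e-12)

    def test_head_on_magnitude_matches_hand_evaluation(self, cfg):
        # equal radii R, overlap depth 0.2 R, zero velocities
        p = cfg.physics
        R = 0.07
        contact = 2 * R
        dist = contact - 0.2 * R
        a = make_body(0, (0.4, 0.5, -0.5), radius=R)
        b = make_body(1, (0.4 + dist, 0.5, -0.5), radius=R)
        f = pair_collision_force(a, b, p)
        # independent evaluation: linear overlap spring + soft-core gradient
        soft = (
            p.soft_core_strength
            * p.soft_core_exponent
            * contact**p.soft_core_exponent
            / dist ** (p.soft_core_exponent + 1)
        )
        soft = min(soft, p.k_spring * contact)
        expected = p.k_spring * (contact - dist) + soft
        np.testing.assert_allclose(np.linalg.norm(f), expected, rtol=1e-12)
        assert f[0] < 0  # repulsive: pushes a away from b


class TestSpringForces:
    def test_no_wall_spring_no_force(self, cfg):
        assert np.array_equal(
            wall_spring_force(np.array([0.5, 0.5, -0.5]), None, cfg.adhesion), np.zeros(3)
        )

    def test_wall_spring_equilibrium_and_hooke(self, cfg):
        a = cfg.adhesion
        pos = np.array([0.5, 0.5, -1.0 + a.L0_wall])
        anchor = np.array([0.5, 0.5, -1.0])
        np.testing.assert_allclose(wall_spring_force(pos, anchor, a), np.zeros(3), atol=1e-12)
        stretched = anchor + np.array([0.0, 0.0, a.L0_wall + 0.1])
        f = wall_spring_force(stretched, anchor, a)
        np.testing.assert_allclose(np.linalg.norm(f), a.k_wall * 0.1, rtol=1e-12)
        assert f[2] < 0  # pulls back toward the anchor

    def test_three_cell_chain_spring_forces_cancel(self, cfg):
        state = random_world(cfg, seed=5, n_cells=3, n_particles=0)
        state.pos[:] = [[0.3, 0.5, -0.5], [0.45, 0.5, -0.5], [0.6, 0.5, -0.52]]
        state.springs.add_pairs(state.ids[[0, 1]], state.ids[[1, 2]])
        total = sum(cell_spring_force(state, int(i), cfg.adhesion) for i in state.ids)
        np.testing.assert_allclose(total, np.zeros(3), atol=1e-12)


class TestTotalForces:
    def test_isolated_resting_cell_zero_force(self):
        cfg = default_config().replace(physics={"sigma": 0.0, "g": (0.0, 0.0, 0.0)})
        state = _single_cell(cfg, pos=(0.5, 0.5, -0.5))
        f = total_cell_force(state, 0, cfg.physics, cfg.adhesion)
        np.testing.assert_allclose(f, np.zeros(3), atol=1e-15)

    def test_isolated_cell_feels_weight(self):
        cfg = default_config().replace(physics={"sigma": 0.0})
        state = _single_cell(cfg, pos=(0.5, 0.5, -0.5))
        f = total_cell_force(state, 0, cfg.physics, cfg.adhesion)
        np.testing.assert_allclose(f, state.mass[0] * np.asarray(cfg.physics.g), atol=1e-15)

    def test_internal_forces_cancel_in_two_cell_overlap(self, cfg):
        state = random_world(cfg, seed=7, n_cells=2, n_particles=0)
        state.pos[:] = [[0.5, 0.5, -0.5], [0.5 + 0.1, 0.5, -0.5]]  # overlapping
        pairs = collect_pairs(state, cfg.physics)
        F, internal_sum = compute_forces(state, cfg.physics, cfg.adhesion, np.zeros(3), pairs)
        np.testing.assert_allclose(internal_sum, np.zeros(3), atol=1e-12)
        # total of both bodies = total gravity + total drag
        expected = (
            state.mass.sum() * np.asarray(cfg.physics.g)
            - cfg.physics.gamma * state.vel.sum(axis=0)
        )
        np.testing.assert_allclose(F.sum(axis=0), expected, atol=1e-12)
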