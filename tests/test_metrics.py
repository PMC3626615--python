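import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chimera.config import default_config
from chimera.metrics import (
    PHASES,
    StepRecord,
    cell_entropy,
    classify_phase,
    detect_top_layer,
    detritivore_stats,
    mean_efficiency,
    population_summary,
)
from chimera.state import init_state

from conftest import random_world


class TestCellEntropy:
    def test_specialist_is_zero(self):
        assert cell_entropy(np.array([1.0, 0, 0, 0, 0])) == 0.0

    def test_uniform_is_one(self):
        assert cell_entropy(np.full(5, 0.2)) == pytest.approx(1.0)

    def test_two_source_value(self):
        expected = math.log(2) / math.log(5)
        assert cell_entropy(np.array([0.5, 0.5, 0, 0, 0])) == pytest.approx(expected)

    def test_zero_vector_is_domain_error(self):
        with pytest.raises(ValueError):
            cell_entropy(np.zeros(5))

    @given(
        vec=st.lists(st.floats(0.0, 1.0), min_size=2, max_size=6).filter(lambda v: sum(v) > 0.01),
        scale=st.floats(0.1, 10.0),
    )
    def test_permutation_and_scale_invariance(self, vec, scale):
        v = np.asarray(vec)
        h = cell_entropy(v)
        assert cell_entropy(v[::-1].copy()) == pytest.approx(h, abs=1e-12)
        assert cell_entropy(scale * v) == pytest.approx(h, abs=1e-12)
        assert 0.0 <= h <= 1.0 + 1e-12


class TestMeanEfficiency:
    def test_specialist(self):
        assert mean_efficiency(np.array([1.0, 0, 0, 0, 0])) == 1.0

    def test_uniform(self):
        assert mean_efficiency(np.full(5, 0.2)) == pytest.approx(0.2)

    def test_three_used_sources(self):
        assert mean_efficiency(np.array([0.5, 0.25, 0.25, 0, 0])) == pytest.approx(1 / 3)

    def test_reciprocal_identity_for_normalized_genomes(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            v = rng.dirichlet(np.ones(5))
            n_used = int((v > 0).sum())
            assert mean_efficiency(v) * n_used == pytest.approx(v.sum())

    def test_zero_vector_is_domain_error(self):
        with pytest.raises(ValueError):
            mean_efficiency(np.zeros(4))


class TestPopulationSummary:
    def test_empty_world_flags_absent_means(self, cfg):
        state = random_world(cfg, seed=0, n_cells=0, n_particles=5)
        rec = population_summary(state)
        assert rec.n_cells == 0
        assert math.isnan(rec.mean_entropy)
        assert math.isnan(rec.mean_height)

    def test_single_founder_on_floor(self, cfg):
        state = init_state(cfg.replace(evolution={"n_founders": 1}), 0)
        rec = population_summary(state)
        assert rec.n_cells == 1
        assert rec.mean_entropy == 0.0  # class-1 specialist
        assert rec.mean_height == pytest.approx(-1.0 + cfg.evolution.cell_radius)

    def test_mean_height_is_arithmetic_mean(self, cfg):
        state = random_world(cfg, seed=1, n_cells=2, n_particles=0)
        state.pos[:, 2] = [-1.0 + 1e-9, -1e-9]
        rec = population_summary(state)
        assert rec.mean_height == pytest.approx(-0.5)


class TestTopLayerDetector:
    def test_empty_world_false(self, cfg):
        state = random_world(cfg, seed=2, n_cells=0, n_particles=3)
        assert detect_top_layer(state) is False

    def test_all_cells_at_top_true(self, cfg):
        state = random_world(cfg, seed=3, n_cells=20, n_particles=0)
        state.pos[:, 2] = -cfg.evolution.cell_radius
        assert detect_top_layer(state) is True

    def test_threshold_arithmetic(self, cfg):
        mp = cfg.metrics
        state = random_world(cfg, seed=4, n_cells=100, n_particles=0)
        state.pos[:, 2] = -0.5
        state.pos[:9, 2] = -mp.band_depth / 2  # 9% in band: below the 10% threshold
        assert detect_top_layer(state) is False
        state.pos[:11, 2] = -mp.band_depth / 2  # 11%: above
        assert detect_top_layer(state) is True


class TestDetritivoreStats:
    def test_founders_have_none(self, cfg):
        state = init_state(cfg, 0)
        count, mean = detritivore_stats(state)
        assert count == 0 and math.isnan(mean)

    def test_single_detritivore(self, cfg):
        state = random_world(cfg, seed=5, n_cells=1, n_particles=0)
        state.eff[0, :] = 0.0
        state.eff[0, -1] = 0.8
        count, mean = detritivore_stats(state)
        assert (count, mean) == (1, pytest.approx(0.8))

    def test_subset_mean_above_eps(self, cfg):
        state = random_world(cfg, seed=6, n_cells=3, n_particles=0)
        state.eff[:, -1] = [0.0, 0.2, 0.6]
        count, mean = detritivore_stats(state, eps=0.1)
        assert count == 2
        assert mean == pytest.approx(0.4)


def _rec(step, n_cells, span=0.0, top=False):
    return StepRecord(
        step=step,
        n_cells=n_cells,
        n_particles_by_class=[0] * 5,
        free_nutrients=0,
        mean_entropy=0.0,
        mean_efficiency=1.0,
        mean_wall_adhesion=0.5,
        mean_cell_adhesion=0.5,
        mean_height=-0.9,
        height_span=span,
        n_detritivores=0,
        mean_detritivore_efficiency=float("nan"),
        top_layer_occupied=top,
    )


class TestClassifyPhase:
    def test_extinction(self, cfg):
        records = [_rec(s, 10) for s in range(5)] + [_rec(5, 0)]
        assert classify_phase(records, cfg) == "extinction"

    def test_een_with_persistent_top_band(self, cfg):
        records = [_rec(s, 50, span=0.9, top=True) for s in range(12)]
        assert classify_phase(records, cfg) == "EEN"

    def test_monolayer_flat_population(self, cfg):
        span = cfg.evolution.cell_radius  # well under two cell diameters
        records = [_rec(s, 50, span=span) for s in range(12)]
        assert classify_phase(records, cfg) == "monolayer"

    def test_multilayer_from_height_span(self, cfg):
        span = 5 * 2 * cfg.evolution.cell_radius
        records = [_rec(s, 50, span=span) for s in range(12)]
        assert classify_phase(records, cfg) == "multilayer"

    def test_total_function_on_random_trajectories(self, cfg):
        rng = np.random.default_rng(7)
        for _ in range(50):
            records = [
                _rec(
                    s,
                    int(rng.integers(0, 30)),
                    span=float(rng.uniform(0, 1)),
                    top=bool(rng.random() < 0.3),
                )
                for s in range(10)
            ]
            assert classify_phase(records, cfg) in PHASES

    def test_empty_trajectory_is_usage_error(self, cfg):
        with pytest.raises(ValueError):
            classify_phase([], cfg)
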