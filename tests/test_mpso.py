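"""Optimizer components: schedules, staged updates, disturbances, benchmarks."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ricespace.mpso import (
    MPSOConfig,
    Particle,
    SwarmState,
    disturbance_probability,
    first_order_disturbance,
    inertia_weight,
    optimize,
    second_order_disturbance,
    update_particle,
)


class ScriptedRNG:
    """Feeds predetermined draws to the update/disturbance operators."""

    def __init__(self, uniforms=(), integers=(), normals=(), ranged=()):
        self._uniforms = list(uniforms)
        self._integers = list(integers)
        self._normals = list(normals)
        self._ranged = list(ranged)

    def random(self, size=None):
        if size is None:
            return self._uniforms.pop(0)
        return np.array([self._uniforms.pop(0) for _ in range(size)])

    def integers(self, *args, **kwargs):
        return self._integers.pop(0)

    def standard_normal(self):
        return self._normals.pop(0)

    def uniform(self, lo, hi, size=None):
        return self._ranged.pop(0)


class TestSchedules:
    def test_inertia_weight_endpoints(self):
        assert inertia_weight(1, 300) == pytest.approx(0.9)
        assert inertia_weight(300, 300) == pytest.approx(0.4)

    def test_inertia_weight_interior_value(self):
        expected = 0.9 - 0.5 * math.log(17) / math.log(300)
        assert inertia_weight(17, 300) == pytest.approx(expected)
        assert inertia_weight(17, 300) == pytest.approx(0.6517, abs=1e-4)

    def test_inertia_weight_monotone_non_increasing(self):
        values = [inertia_weight(t, 200) for t in range(1, 201)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("t", [0, 301])
    def test_inertia_weight_domain(self, t):
        with pytest.raises(ValueError):
            inertia_weight(t, 300)

    def test_disturbance_probability_endpoints(self):
        assert disturbance_probability(0, 300) == pytest.approx(0.5)
        assert disturbance_probability(300, 300) == pytest.approx(0.0)

    def test_disturbance_probability_midpoint(self):
        assert disturbance_probability(150, 300) == pytest.approx(
            math.cos(math.pi / 4) / 2
        )

    def test_disturbance_probability_monotone(self):
        values = [disturbance_probability(k, 120) for k in range(121)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(0.0 <= v <= 0.5 for v in values)

    def test_disturbance_probability_domain(self):
        with pytest.raises(ValueError):
            disturbance_probability(301, 300)


class TestVelocityUpdate:
    CFG = MPSOConfig(bounds=(0.0, 20.0), v_max_frac=1.0, t_max=100, t_switch=50,
                     omega_constant=0.7)

    def test_exploration_stage_hand_computed(self):
        p = Particle(x=10.0, v=0.5, pbest_x=12.0, pbest_f=1.0)
        rng = ScriptedRNG(uniforms=[0.5, 0.25])
        out = update_particle(p, 14.0, k=10, cfg=self.CFG, rng=rng)
        # v' = 0.7*0.5 + 2*0.5*(12-10) + 2*0.25*(14-10) = 4.35
        assert out.v == pytest.approx(4.35, abs=1e-12)
        assert out.x == pytest.approx(14.35, abs=1e-12)

    def test_convergence_stage_hand_computed(self):
        p = Particle(x=10.0, v=0.5, pbest_x=12.0, pbest_f=1.0)
        rng = ScriptedRNG(uniforms=[0.5, 0.25])
        out = update_particle(p, 14.0, k=60, cfg=self.CFG, rng=rng)
        # v' = 0.729*(0.5 + 2 + 2) = 3.2805
        assert out.v == pytest.approx(3.2805, abs=1e-12)
        assert out.x == pytest.approx(13.2805, abs=1e-12)

    def test_pure_inertia_when_learning_factors_zero(self):
        cfg = MPSOConfig(bounds=(0.0, 20.0), v_max_frac=1.0, t_max=100,
                         t_switch=50, omega_constant=1.0, c1=0.0, c2=0.0)
        p = Particle(x=10.0, v=0.5, pbest_x=3.0, pbest_f=1.0)
        out = update_particle(p, 18.0, k=10, cfg=cfg, rng=ScriptedRNG([0.9, 0.9]))
        assert out.v == 0.5
        assert out.x == 10.5

    def test_velocity_capped(self):
        cfg = MPSOConfig(bounds=(0.0, 100.0), v_max_frac=0.01, t_max=100,
                         t_switch=50, omega_constant=0.7)
        p = Particle(x=10.0, v=0.5, pbest_x=90.0, pbest_f=1.0)
        out = update_particle(p, 90.0, k=10, cfg=cfg, rng=ScriptedRNG([1.0, 1.0]))
        assert abs(out.v) <= cfg.v_max + 1e-15

    def test_position_clipped_with_velocity_zeroed(self):
        p = Particle(x=19.0, v=5.0, pbest_x=19.0, pbest_f=1.0)
        cfg = MPSOConfig(bounds=(0.0, 20.0), v_max_frac=1.0, t_max=100,
                         t_switch=50, omega_constant=1.0, c1=0.0, c2=0.0)
        out = update_particle(p, 19.0, k=10, cfg=cfg, rng=ScriptedRNG([0.1, 0.1]))
        assert out.x == 20.0
        assert out.v == 0.0


class TestFirstOrderDisturbance:
    CFG = MPSOConfig(bounds=(5.0, 50.0), t_max=100, t_switch=50)

    def test_exploration_reset_rule_stays_in_bounds(self):
        p = Particle(x=20.0, v=1.0, pbest_x=20.0, pbest_f=1.0)
        rng = ScriptedRNG(integers=[3], ranged=[33.3])
        out = first_order_disturbance(p, k=10, cfg=self.CFG, rng=rng)
        assert out.x == 33.3
        assert out.v == 1.0  # velocity preserved

    def test_convergence_average_rule_arithmetic(self):
        p = Particle(x=20.0, v=1.0, pbest_x=20.0, pbest_f=1.0)
        rng = ScriptedRNG(uniforms=[0.5, 0.7], integers=[1])
        out = first_order_disturbance(p, k=60, cfg=self.CFG, rng=rng)
        assert out.x == pytest.approx(12.0)

    def test_gaussian_rule_negative_draw_clips_to_lower_bound(self):
        p = Particle(x=20.0, v=1.0, pbest_x=20.0, pbest_f=1.0)
        rng = ScriptedRNG(integers=[2], normals=[-1.3])
        out = first_order_disturbance(p, k=10, cfg=self.CFG, rng=rng)
        assert out.x == 5.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 99),
           x=st.floats(5.0, 50.0))
    def test_result_always_in_bounds(self, seed, k, x):
        p = Particle(x=x, v=0.0, pbest_x=x, pbest_f=0.0)
        out = first_order_disturbance(
            p, k, self.CFG, np.random.default_rng(seed)
        )
        assert 5.0 <= out.x <= 50.0


class TestSecondOrderDisturbance:
    CFG = MPSOConfig(bounds=(5.0, 50.0), t_max=100, t_switch=50, n_particles=3)

    def _state(self, history):
        particles = [Particle(x=10.0, v=0.0, pbest_x=10.0) for _ in range(3)]
        return SwarmState(particles=particles, gbest_x=history[-1],
                          gbest_history=list(history), stagnation_count=12)

    def test_scatter_arithmetic(self):
        state = self._state([18.0, 19.0])
        rng = ScriptedRNG(ranged=[0.5, 0.5, 0.5])
        new_x = second_order_disturbance(state, self.CFG, rng)
        assert new_x == pytest.approx([18.5, 18.5, 18.5])
        assert state.stagnation_count == 0

    @pytest.mark.parametrize("ra", [0.0, -2.0])
    def test_nonpositive_draws_clip_to_lower_bound(self, ra):
        state = self._state([18.0, 19.0])
        rng = ScriptedRNG(ranged=[ra, ra, ra])
        assert second_order_disturbance(state, self.CFG, rng) == pytest.approx(
            [5.0, 5.0, 5.0]
        )

    def test_short_history_uses_single_best_twice(self):
        state = self._state([21.0])
        rng = ScriptedRNG(ranged=[0.5, 0.5, 0.5])
        assert second_order_disturbance(state, self.CFG, rng) == pytest.approx(
            [21.0, 21.0, 21.0]
        )


def _canonical_pso(objective, seed, n, t_max, bounds, omega, c1, c2, v_max):
    """Plain inertia-weight PSO, written straight from the textbook update."""
    rng = np.random.default_rng(seed)
    lo, hi = bounds
    x = rng.uniform(lo, hi, n)
    v = rng.uniform(-v_max, v_max, n)
    pbest_x = x.copy()
    pbest_f = np.full(n, -np.inf)
    gbest_x, gbest_f = math.nan, -math.inf
    history = []
    for _ in range(t_max):
        for i in range(n):
            f = objective(x[i])
            if f > pbest_f[i]:
                pbest_f[i], pbest_x[i] = f, x[i]
            if f > gbest_f:
                gbest_f, gbest_x = f, x[i]
        for i in range(n):
            r1 = rng.random()
            r2 = rng.random()
            v[i] = omega * v[i] + c1 * r1 * (pbest_x[i] - x[i]) + c2 * r2 * (gbest_x - x[i])
            v[i] = max(-v_max, min(v_max, v[i]))
            x[i] = x[i] + v[i]
            if x[i] < lo:
                x[i], v[i] = lo, 0.0
            elif x[i] > hi:
                x[i], v[i] = hi, 0.0
        history.append(x.copy())
    return history, gbest_x, gbest_f


class TestOptimize:
    def test_quadratic_converges_across_seeds(self):
        hits = 0
        for seed in range(10):
            cfg = MPSOConfig(n_particles=15, t_max=150, bounds=(0.0, 20.0),
                             t_switch_range=(38, 113), seed=seed)
            result = optimize(lambda x: -((x - 7.0) ** 2), cfg)
            hits += abs(result.best_x - 7.0) < 0.05
        assert hits >= 9

    def test_constant_objective_triggers_second_order_by_iteration_11(self):
        cfg = MPSOConfig(n_particles=5, t_max=20, bounds=(0.0, 10.0),
                         t_switch=10, seed=3)
        result = optimize(lambda x: 1.0, cfg)
        events = [row.event for row in result.trace.rows]
        assert "second_order" in events
        assert events.index("second_order") + 1 <= 11

    def test_gbest_non_decreasing(self):
        cfg = MPSOConfig(n_particles=10, t_max=80, bounds=(0.0, 20.0),
                         t_switch=40, seed=1)
        result = optimize(lambda x: math.sin(x) * x, cfg)
        f = result.trace.gbest_fitness()
        assert all(a <= b for a, b in zip(f, f[1:]))

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_positions_stay_in_bounds_throughout(self, seed):
        cfg = MPSOConfig(n_particles=6, t_max=40, bounds=(2.0, 9.0),
                         t_switch=20, seed=seed, record_particles=True,
                         stagnation_threshold=3)
        result = optimize(lambda x: math.cos(3 * x), cfg)
        for row in result.trace.rows:
            assert all(2.0 <= x <= 9.0 for x in row.positions)

    def test_objective_error_reports_context(self):
        def bad(x):
            raise ZeroDivisionError("boom")

        cfg = MPSOConfig(n_particles=3, t_max=5, bounds=(0.0, 1.0), t_switch=3, seed=0)
        with pytest.raises(RuntimeError, match="iteration 1, particle 0"):
            optimize(bad, cfg)

    def test_t_switch_drawn_from_configured_range(self):
        cfg = MPSOConfig(n_particles=5, t_max=300, bounds=(0.0, 20.0), seed=11)
        result = optimize(lambda x: -((x - 3.0) ** 2), cfg)
        assert 75 <= result.t_switch <= 225
        assert result.trace.metadata["t_switch"] == result.t_switch

    def test_reduces_to_canonical_pso_without_disturbances(self):
        objective = lambda x: -((x - 13.0) ** 2)
        seed, n, t_max, bounds, omega = 5, 8, 60, (0.0, 20.0), 0.7
        cfg = MPSOConfig(
            n_particles=n, t_max=t_max, bounds=bounds, seed=seed,
            t_switch=t_max + 1, omega_constant=omega,
            disturbances_enabled=False, record_particles=True, v_max_frac=0.2,
        )
        result = optimize(objective, cfg)
        history, gx, gf = _canonical_pso(
            objective, seed, n, t_max, bounds, omega, cfg.c1, cfg.c2, cfg.v_max
        )
        for row, ref in zip(result.trace.rows, history):
            assert tuple(ref) == row.positions  # bit-identical trajectories
        assert result.best_x == gx
        assert result.best_f == gf
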