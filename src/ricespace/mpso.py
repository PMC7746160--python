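"""Mixed particle swarm optimization (MPSO) with multistage disturbances.

The optimizer runs in two stages split at a switching point T: before T it
uses the classic inertia-weight velocity update and strong first-order
disturbances to explore; from T on it uses a constriction-factor update and
weak disturbances to converge.  Two disturbance mechanisms guard against
local optima:

* first-order: each iteration, each particle is re-positioned with a
  probability that decays as cos(pi k / (2 t_max)) / 2, using a random rule
  from the active stage's rule set (aggressive rescalings or a full reset
  pre-switch; mild contractions post-switch);
* second-order: when the global best has stagnated for a run of
  ``stagnation_threshold`` iterations, every particle is thrown to
  (g[-2] + g[-1]) * ra with ra ~ U(-2, 2) drawn per particle, where g[-2],
  g[-1] are the two most recent global-best positions.

The inertia weight decays logarithmically from 0.9 at the first iteration
to 0.4 at the last.  The optimizer maximises the objective over a 1-D box.
"""

from __future__ import annotations

import inspect
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

from .trace import OptimizationTrace, TraceRow

__all__ = [
    "MPSOConfig",
    "Particle",
    "SwarmState",
    "OptimizeResult",
    "inertia_weight",
    "disturbance_probability",
    "update_particle",
    "first_order_disturbance",
    "second_order_disturbance",
    "optimize",
    "derive_eval_seed",
]


@dataclass(frozen=True)
class MPSOConfig:
    """Optimizer settings.

    ``t_switch`` left as None is drawn uniformly from ``t_switch_range`` at
    run start.  ``omega_constant`` pins the inertia weight (used with
    ``disturbances_enabled=False`` to reduce the algorithm to canonical
    PSO).  ``init_bounds`` restricts only the initial particle positions;
    the search box stays ``bounds``.
    """

    n_particles: int = 20
    t_max: int = 300
    t_switch: int | None = None
    t_switch_range: tuple[int, int] = (75, 225)
    c1: float = 2.0
    c2: float = 2.0
    phi: float = 0.729
    omega_start: float = 0.9
    omega_end: float = 0.4
    stagnation_threshold: int = 10
    stagnation_rel_tol: float = 1e-9
    bounds: tuple[float, float] = (5.0, 50.0)
    v_max_frac: float = 0.2
    seed: int = 0
    disturbances_enabled: bool = True
    omega_constant: float | None = None
    init_bounds: tuple[float, float] | None = None
    record_particles: bool = False

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError(f"n_particles must be >= 2, got {self.n_particles}")
        if self.t_max < 2:
            raise ValueError(f"t_max must be >= 2, got {self.t_max}")
        if self.t_switch is not None and self.t_switch < 1:
            raise ValueError(
                f"t_switch must be a positive iteration index, got {self.t_switch}"
            )
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError(f"bounds must satisfy lower < upper, got {self.bounds}")
        if self.stagnation_threshold < 1:
            raise ValueError("stagnation_threshold must be >= 1")
        if self.v_max_frac <= 0:
            raise ValueError("v_max_frac must be > 0")

    @property
    def v_max(self) -> float:
        return self.v_max_frac * (self.bounds[1] - self.bounds[0])


@dataclass
class Particle:
    """Position (a spacing candidate), velocity, and personal best."""

    x: float
    v: float
    pbest_x: float
    pbest_f: float = -math.inf


@dataclass
class SwarmState:
    """Full swarm state at iteration ``k``."""

    particles: list[Particle]
    gbest_x: float = math.nan
    gbest_f: float = -math.inf
    gbest_history: list[float] = field(default_factory=list)
    k: int = 0
    stagnation_count: int = 0


@dataclass(frozen=True)
class OptimizeResult:
    best_x: float
    best_f: float
    t_switch: int
    trace: OptimizationTrace


def inertia_weight(
    t_current: int,
    t_max: int,
    omega_start: float = 0.9,
    omega_end: float = 0.4,
) -> float:
    """Logarithmically decaying inertia weight.

    omega = omega_start - (omega_start - omega_end) * ln(t) / ln(t_max),
    i.e. a log of base t_max, so omega sweeps omega_start -> omega_end over
    the run; clamped to [omega_end, omega_start] for safety.
    """
    if t_max < 2:
        raise ValueError(f"t_max must be >= 2, got {t_max}")
    if not 1 <= t_current <= t_max:
        raise ValueError(
            f"t_current must lie in [1, t_max]={t_max}, got {t_current}"
        )
    omega = omega_start - (omega_start - omega_end) * math.log(t_current) / math.log(t_max)
    return min(omega_start, max(omega_end, omega))


def disturbance_probability(k: int, t_max: int) -> float:
    """Probability of a first-order disturbance at iteration ``k``.

    pr = cos(pi k / (2 t_max)) / 2: one half at the start, zero at the end,
    monotone non-increasing.
    """
    if not 0 <= k <= t_max:
        raise ValueError(f"k must lie in [0, t_max]={t_max}, got {k}")
    return math.cos(math.pi * k / (2.0 * t_max)) / 2.0


def _clip_position(x: float, v: float, bounds: tuple[float, float]) -> tuple[float, float]:
    """Clip ``x`` into bounds; a clipped particle has its velocity zeroed."""
    lo, hi = bounds
    if x < lo:
        return lo, 0.0
    if x > hi:
        return hi, 0.0
    return x, v


def update_particle(
    p: Particle,
    gbest_x: float,
    k: int,
    cfg: MPSOConfig,
    rng: np.random.Generator,
) -> Particle:
    """Staged velocity/position update.

    Before the switching point: inertia-weight form
    v' = omega v + c1 r1 (pbest - x) + c2 r2 (gbest - x); from the switching
    point on: constriction form v' = phi (v + c1 r1 (pbest - x) +
    c2 r2 (gbest - x)).  The velocity is capped at v_max and the position is
    clipped into bounds with the velocity zeroed on clip.
    """
    t_switch = cfg.t_switch if cfg.t_switch is not None else cfg.t_max
    r1 = rng.random()
    r2 = rng.random()
    if k < t_switch:
        omega = (
            cfg.omega_constant
            if cfg.omega_constant is not None
            else inertia_weight(max(k, 1), cfg.t_max, cfg.omega_start, cfg.omega_end)
        )
        v_new = (
            omega * p.v
            + cfg.c1 * r1 * (p.pbest_x - p.x)
            + cfg.c2 * r2 * (gbest_x - p.x)
        )
    else:
        v_new = cfg.phi * (
            p.v + cfg.c1 * r1 * (p.pbest_x - p.x) + cfg.c2 * r2 * (gbest_x - p.x)
        )
    v_new = max(-cfg.v_max, min(cfg.v_max, v_new))
    x_new, v_new = _clip_position(p.x + v_new, v_new, cfg.bounds)
    return replace(p, x=x_new, v=v_new)


def first_order_disturbance(
    p: Particle, k: int, cfg: MPSOConfig, rng: np.random.Generator
) -> Particle:
    """Re-position a particle by one randomly chosen stage rule.

    Exploration stage (k < t_switch), rule set A:
    x' = r0 x | (r1 + r2) r3 x | ga x | fresh uniform draw in bounds,
    with r* ~ U(0, 1) and ga standard normal.  Convergence stage, rule set
    B: x' = r1 x | ((r1 + r2) / 2) x.  The result is clipped into bounds;
    the velocity is preserved.
    """
    t_switch = cfg.t_switch if cfg.t_switch is not None else cfg.t_max
    lo, hi = cfg.bounds
    stage = "A" if k < t_switch else "B"
    if k < t_switch:
        rule = int(rng.integers(4))
        if rule == 0:
            x_new = rng.random() * p.x
        elif rule == 1:
            r1, r2, r3 = rng.random(3)
            x_new = (r1 + r2) * r3 * p.x
        elif rule == 2:
            x_new = rng.standard_normal() * p.x
        else:  # reset to a fresh position in the solution domain
            x_new = rng.uniform(lo, hi)
    else:
        rule = int(rng.integers(2))
        if rule == 0:
            x_new = rng.random() * p.x
        else:
            r1, r2 = rng.random(2)
            x_new = 0.5 * (r1 + r2) * p.x
    x_new = min(hi, max(lo, x_new))
    logger.debug("first-order disturbance: stage %s rule %d, x %.4f -> %.4f",
                 stage, rule, p.x, x_new)
    return replace(p, x=x_new)


def second_order_disturbance(
    state: SwarmState, cfg: MPSOConfig, rng: np.random.Generator
) -> np.ndarray:
    """Stagnation rescue: scatter all particles around recent global bests.

    Per particle, x' = (g[-2] + g[-1]) * ra with ra ~ U(-2, 2) and g[-2],
    g[-1] the two most recent global-best positions (the single best is used
    twice when the history is shorter).  Positions are clipped into bounds
    and the stagnation counter resets.
    """
    hist = state.gbest_history
    if len(hist) >= 2:
        g2, g1 = hist[-2], hist[-1]
    else:
        g2 = g1 = hist[-1] if hist else state.gbest_x
    lo, hi = cfg.bounds
    new_x = np.empty(len(state.particles))
    for i in range(len(state.particles)):
        ra = rng.uniform(-2.0, 2.0)
        new_x[i] = min(hi, max(lo, (g2 + g1) * ra))
    state.stagnation_count = 0
    return new_x


def derive_eval_seed(run_seed: int, k: int, i: int) -> int:
    """Deterministic per-evaluation seed from (run seed, iteration, particle)."""
    return int(
        np.random.SeedSequence([abs(int(run_seed)), int(k), int(i)]).generate_state(1)[0]
        & 0x7FFFFFFF
    )


def _objective_accepts_seed(objective: Callable) -> bool:
    try:
        sig = inspect.signature(objective)
    except (TypeError, ValueError):
        return False
    params = sig.parameters
    return "seed" in params or any(
        p.kind is inspect.Parameter.VAR_KEYWORD for p in params.values()
    )


def optimize(objective: Callable, cfg: MPSOConfig) -> OptimizeResult:
    """Maximise ``objective`` over ``cfg.bounds`` with MPSO.

    ``objective`` is called as ``objective(x, seed=...)`` when it accepts a
    ``seed`` keyword (the seed is derived deterministically from
    ``(cfg.seed, iteration, particle index)``, making stochastic objectives
    exactly repeatable), otherwise as ``objective(x)``.

    Each iteration evaluates all particles and updates the bests, then
    either applies a second-order disturbance to the whole swarm (when the
    global best stagnated for ``stagnation_threshold`` iterations), or
    updates each particle — by a first-order disturbance with the decaying
    probability, by the staged velocity rule otherwise.  The returned trace
    has one row per iteration; the global best is non-decreasing.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.t_switch is not None:
        t_switch = cfg.t_switch
    else:
        lo_t, hi_t = cfg.t_switch_range
        if not 0 < lo_t <= hi_t <= cfg.t_max:
            raise ValueError(
                f"t_switch_range {cfg.t_switch_range} must lie within (0, t_max]"
            )
        t_switch = int(rng.integers(lo_t, hi_t + 1))
    run_cfg = replace(cfg, t_switch=t_switch)

    lo, hi = cfg.bounds
    init_lo, init_hi = cfg.init_bounds if cfg.init_bounds is not None else cfg.bounds
    xs = rng.uniform(init_lo, init_hi, cfg.n_particles)
    vs = rng.uniform(-cfg.v_max, cfg.v_max, cfg.n_particles)
    state = SwarmState(
        particles=[Particle(x=float(x), v=float(v), pbest_x=float(x)) for x, v in zip(xs, vs)]
    )
    pass_seed = _objective_accepts_seed(objective)
    trace = OptimizationTrace(
        metadata={"seed": cfg.seed, "t_switch": t_switch, "t_max": cfg.t_max}
    )

    prev_gbest = -math.inf
    for k in range(1, cfg.t_max + 1):
        state.k = k
        for i, p in enumerate(state.particles):
            try:
                if pass_seed:
                    f = float(objective(p.x, seed=derive_eval_seed(cfg.seed, k, i)))
                else:
                    f = float(objective(p.x))
            except Exception as exc:
                raise RuntimeError(
                    f"objective failed at iteration {k}, particle {i}, x={p.x!r}: {exc}"
                ) from exc
            if f > p.pbest_f:
                p.pbest_f = f
                p.pbest_x = p.x
            if f > state.gbest_f:
                state.gbest_f = f
                state.gbest_x = p.x
        state.gbest_history.append(state.gbest_x)

        improvement = state.gbest_f - prev_gbest
        tol = cfg.stagnation_rel_tol * max(1.0, abs(prev_gbest))
        if math.isfinite(prev_gbest) and improvement < tol:
            state.stagnation_count += 1
        else:
            state.stagnation_count = 0
        prev_gbest = state.gbest_f

        event = "none"
        if (
            cfg.disturbances_enabled
            and state.stagnation_count >= cfg.stagnation_threshold
        ):
            new_x = second_order_disturbance(state, run_cfg, rng)
            for p, x in zip(state.particles, new_x):
                p.x = float(x)
            event = "second_order"
        else:
            for i, p in enumerate(state.particles):
                if cfg.disturbances_enabled and rng.random() < disturbance_probability(
                    k, cfg.t_max
                ):
                    state.particles[i] = first_order_disturbance(p, k, run_cfg, rng)
                    event = "first_order"
                else:
                    state.particles[i] = update_particle(
                        p, state.gbest_x, k, run_cfg, rng
                    )

        logger.info(
            "iteration %d: gbest_x=%.4f gbest_f=%.6g event=%s stagnation=%d",
            k, state.gbest_x, state.gbest_f, event, state.stagnation_count,
        )
        trace.append(
            TraceRow(
                iteration=k,
                gbest_x=state.gbest_x,
                gbest_f=state.gbest_f,
                event=event,
                positions=(
                    tuple(p.x for p in state.particles)
                    if cfg.record_particles
                    else None
                ),
            )
        )

    return OptimizeResult(
        best_x=state.gbest_x, best_f=state.gbest_f, t_switch=t_switch, trace=trace
    )
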