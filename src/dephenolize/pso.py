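"""Particle swarm optimization over the extraction-condition box.

The swarm configuration mirrors the published optimization setup: 20
particles, 800 iterations, personal coefficient c1 = 1.5, global
coefficient c2 = 2.0, constant inertia weight (the Clerc constriction value
0.729 by default). An initial-span setting larger than the process box on
every axis reduces to uniform initialization within bounds, which is what
this implementation does. Bound handling is absorbing: positions are
clamped to the box and the violating velocity component is zeroed.

``pso_minimize`` is the primitive (minimization); ``optimize_surrogate``
maximizes a fitted surrogate's predicted yield by minimizing its negation,
with restart-stability reporting, and ``grid_oracle`` is the brute-force
lattice search used to verify the swarm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import ExtractionCondition, ProcessBounds

__all__ = ["PSOConfig", "PSOResult", "pso_minimize", "optimize_surrogate", "grid_oracle"]

RESTART_SPREAD_LIMIT = 5.0  # % — published restart-stability criterion


@dataclass(frozen=True)
class PSOConfig:
    swarm_size: int = 20
    max_iter: int = 800
    c1: float = 1.5        # personal (cognitive) coefficient
    c2: float = 2.0        # global (social) coefficient
    inertia: float = 0.729
    seed: int = 0
    initial_span: ProcessBounds | None = None  # None: initialize within bounds

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if not (self.c1 > 0 and self.c2 > 0):
            raise ValueError("c1 and c2 must be positive")
        if not (0.0 < self.inertia < 1.2):
            raise ValueError("inertia must lie in (0, 1.2)")


@dataclass
class PSOResult:
    best_x: np.ndarray
    best_f: float
    history: np.ndarray = field(repr=False)  # best-ever objective per iteration
    n_evals: int = 0
    restart_spread: float = 0.0   # 100*(max-min)/|max| of per-restart bests, %
    per_restart_best: list[float] = field(default_factory=list)
    spread_exceeded: bool = False

    @property
    def best_condition(self) -> ExtractionCondition:
        return ExtractionCondition.from_array(self.best_x)


def pso_minimize(objective, bounds: ProcessBounds, config: PSOConfig) -> PSOResult:
    """Minimize a batch objective f((m, d) array) -> (m,) over the box.

    Velocity update per particle and dimension:
    v <- inertia*v + c1*r1*(pbest - x) + c2*r2*(gbest - x), r1, r2 ~ U(0,1);
    |v| is capped at the per-axis range. Deterministic per config.seed.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = bounds.lower, bounds.upper
    span = hi - lo
    m, d = config.swarm_size, lo.size

    init = config.initial_span or bounds
    x = rng.uniform(
        np.maximum(init.lower, lo), np.minimum(init.upper, hi), size=(m, d)
    )
    v = rng.uniform(-span / 2.0, span / 2.0, size=(m, d))

    f = np.asarray(objective(x), dtype=float)
    if np.any(np.isnan(f)):
        raise ValueError(f"objective returned NaN at {x[np.isnan(f)][0]}")
    n_evals = m
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest_x, gbest_f = x[g].copy(), float(f[g])
    history = [gbest_f]

    for _ in range(config.max_iter):
        r1 = rng.uniform(size=(m, d))
        r2 = rng.uniform(size=(m, d))
        v = (
            config.inertia * v
            + config.c1 * r1 * (pbest_x - x)
            + config.c2 * r2 * (gbest_x - x)
        )
        np.clip(v, -span, span, out=v)
        x = x + v
        # absorbing bounds: clamp and zero the violating velocity component
        low_hit = x < lo
        high_hit = x > hi
        v[low_hit | high_hit] = 0.0
        np.clip(x, lo, hi, out=x)

        f = np.asarray(objective(x), dtype=float)
        if np.any(np.isnan(f)):
            raise ValueError(f"objective returned NaN at {x[np.isnan(f)][0]}")
        n_evals += m
        better = f < pbest_f
        pbest_x[better] = x[better]
        pbest_f[better] = f[better]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        history.append(gbest_f)

    return PSOResult(
        best_x=gbest_x, best_f=gbest_f, history=np.asarray(history), n_evals=n_evals
    )


def optimize_surrogate(
    fit,
    bounds: ProcessBounds | None = None,
    config: PSOConfig | None = None,
    n_restarts: int = 5,
) -> PSOResult:
    """Maximize a fitted surrogate's predicted yield with restart checking.

    Runs ``n_restarts`` independently seeded swarms (restart r uses seed
    config.seed + r) and reports the overall best as a maximization result:
    ``best_f`` is the predicted yield (mg GAE/100 g), ``history`` the running
    best per iteration of the winning restart, and ``restart_spread`` the
    max relative difference 100*(max-min)/|max| of the per-restart bests,
    flagged when it exceeds the 5% stability criterion.
    """
    bounds = bounds or ProcessBounds()
    config = config or PSOConfig()
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    def neg(x):
        return -np.asarray(fit.predict(x), dtype=float)

    runs = []
    for r in range(n_restarts):
        cfg = PSOConfig(
            swarm_size=config.swarm_size,
            max_iter=config.max_iter,
            c1=config.c1,
            c2=config.c2,
            inertia=config.inertia,
            seed=config.seed + r,
            initial_span=config.initial_span,
        )
        runs.append(pso_minimize(neg, bounds, cfg))

    bests = [-run.best_f for run in runs]  # predicted yields, maximization scale
    winner = runs[int(np.argmax(bests))]
    hi, lo_b = max(bests), min(bests)
    spread = 0.0 if hi == 0 else 100.0 * (hi - lo_b) / abs(hi)
    return PSOResult(
        best_x=winner.best_x,
        best_f=hi,
        history=-winner.history,
        n_evals=sum(run.n_evals for run in runs),
        restart_spread=spread,
        per_restart_best=bests,
        spread_exceeded=spread > RESTART_SPREAD_LIMIT,
    )


def grid_oracle(objective, bounds: ProcessBounds, n_per_axis: int = 101):
    """Exhaustive maximization on the n^3 lattice spanning the box.

    Ties are broken by the first index in row-major order. Returns
    (x (3,), f). Brute-force verification oracle for the swarm.
    """
    if n_per_axis < 11:
        raise ValueError("n_per_axis must be >= 11")
    axes = [np.linspace(lo, hi, n_per_axis) for lo, hi in bounds.ranges()]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vals = np.asarray(objective(grid), dtype=float)
    i = int(np.argmax(vals))
    return grid[i], float(vals[i])
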