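"""Hybrid hyperparameter search: Hyperband pre-filter, then particle swarm.

Hyperband runs successive-halving brackets of randomly sampled
configurations at growing resource (training epochs) and returns the
bounding box of the top survivors, inflated by 10% and clipped to the
original box — a cheap way to shrink the search space before the swarm
runs.  PSO then maximizes the objective (validation accuracy) with the
classic velocity rule

    v <- w*v + c1*r1*(pbest - p) + c2*r2*(gbest - p),   p <- p + v

under a linearly decaying inertia weight (0.9 -> 0.4 over 50 iterations by
default, swarm of 30, c1 = c2 = 2.0).  Discrete dimensions (layer counts,
unit counts, batch size) are searched in continuous relaxation and rounded
at evaluation and decode time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .nn import HyperParams


@dataclass
class SearchSpace:
    """Named box bounds; ``integer[i]`` marks dimensions rounded at evaluation."""

    names: list[str]
    lower: np.ndarray
    upper: np.ndarray
    integer: list[bool]

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if not (self.lower < self.upper).all():
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def ndim(self) -> int:
        return len(self.names)

    def round(self, x: np.ndarray) -> np.ndarray:
        out = np.array(x, dtype=float)
        for i, is_int in enumerate(self.integer):
            if is_int:
                out[i] = np.clip(round(out[i]), self.lower[i], self.upper[i])
        return out

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.ndim))


def default_search_space() -> SearchSpace:
    """The model's tuning ranges: layers 1-3, units 64-256, dropout 0.2-0.5,
    dense units 32-128, batch size 32-128."""
    return SearchSpace(
        names=["units_per_layer", "dense_units", "dropout", "n_recurrent_layers", "batch_size"],
        lower=np.array([64, 32, 0.2, 1, 32]),
        upper=np.array([256, 128, 0.5, 3, 128]),
        integer=[True, True, False, True, True],
    )


def decode_hyperparams(space: SearchSpace, x: np.ndarray, learning_rate: float = 0.001) -> HyperParams:
    vals = dict(zip(space.names, space.round(x)))
    return HyperParams(
        n_recurrent_layers=int(vals.get("n_recurrent_layers", 2)),
        units_per_layer=int(vals.get("units_per_layer", 128)),
        dropout=float(vals.get("dropout", 0.3)),
        dense_units=int(vals.get("dense_units", 64)),
        batch_size=int(vals.get("batch_size", 32)),
        learning_rate=learning_rate,
    )


@dataclass
class PSOConfig:
    swarm_size: int = 30
    iterations: int = 50
    c1: float = 2.0
    c2: float = 2.0
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.swarm_size, self.iterations) <= 0 or min(self.c1, self.c2) < 0:
            raise ValueError("swarm_size/iterations must be positive, c1/c2 non-negative")
        if not self.inertia_start > self.inertia_end:
            raise ValueError("inertia must decay: inertia_start > inertia_end")


@dataclass
class Swarm:
    positions: np.ndarray  # n x d
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float


@dataclass
class OptimizeResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)  # gbest fitness per iteration
    evaluations: int = 0
    narrowed_space: SearchSpace | None = None

    def best_hyperparams(self, space: SearchSpace) -> HyperParams:
        return decode_hyperparams(space, self.best_position)


def inertia_schedule(t: int, total: int, w0: float = 0.9, w1: float = 0.4) -> float:
    """Linear inertia decay: w(t) = w0 - (w0 - w1) * t / (total - 1)."""
    if total < 2:
        raise ValueError("need at least 2 iterations for a schedule")
    if not 0 <= t <= total - 1:
        raise ValueError(f"iteration index {t} outside [0, {total - 1}]")
    return w0 - (w0 - w1) * t / (total - 1)


def pso_update(
    swarm: Swarm,
    space: SearchSpace,
    w: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
) -> Swarm:
    """One velocity/position step for every particle (in place).

    Per-dimension uniform r1, r2; positions clipped to the box with the
    velocity zeroed on any clipped dimension; velocities clamped to half
    the box range.
    """
    n, d = swarm.positions.shape
    r1 = rng.random((n, d))
    r2 = rng.random((n, d))
    swarm.velocities = (
        w * swarm.velocities
        + c1 * r1 * (swarm.pbest_positions - swarm.positions)
        + c2 * r2 * (swarm.gbest_position - swarm.positions)
    )
    vmax = (space.upper - space.lower) / 2
    swarm.velocities = np.clip(swarm.velocities, -vmax, vmax)
    new_pos = swarm.positions + swarm.velocities
    clipped = np.clip(new_pos, space.lower, space.upper)
    swarm.velocities[clipped != new_pos] = 0.0
    swarm.positions = clipped
    return swarm


def hyperband_prefilter(
    space: SearchSpace,
    objective: Callable[[np.ndarray, float], float],
    max_resource: float = 27,
    eta: float = 3.0,
    seed: int = 0,
    top_q: int | None = None,
    inflate: float = 0.10,
) -> SearchSpace:
    """Successive-halving brackets; returns a narrowed box inside ``space``.

    ``objective(x, resource)`` must be evaluable at reduced resource (e.g.
    fewer training epochs).  The box spanned by the top-q surviving
    configurations (default max(3, 10% of evaluations)) is inflated by
    ``inflate`` of its width per side and intersected with the original box.
    """
    if max_resource < 1:
        raise ValueError("max_resource must allow at least one evaluation")
    rng = np.random.default_rng(seed)
    s_max = int(np.floor(np.log(max_resource) / np.log(eta)))
    scored: list[tuple[float, int, np.ndarray]] = []
    order = 0
    for s in range(s_max, -1, -1):
        n = int(np.ceil((s_max + 1) / (s + 1) * eta**s))
        r = max_resource * eta**-s
        configs = [space.round(x) for x in space.sample(rng, n)]
        fitness = np.array([objective(x, r) for x in configs])
        for rung in range(s + 1):
            for x, f in zip(configs, fitness):
                scored.append((float(f), order, x))
                order += 1
            keep = max(1, int(np.floor(len(configs) / eta)))
            top = np.argsort(-fitness, kind="stable")[:keep]
            configs = [configs[i] for i in top]
            if rung < s:
                r_next = r * eta ** (rung + 1)
                fitness = np.array([objective(x, min(r_next, max_resource)) for x in configs])
            else:
                break
    if top_q is None:
        top_q = max(3, int(np.ceil(0.10 * len(scored))))
    # best fitness per distinct configuration; ties broken by earlier evaluation
    best: dict[tuple, tuple[float, int, np.ndarray]] = {}
    for f, order_i, x in scored:
        key = tuple(np.round(x, 12))
        if key not in best or f > best[key][0]:
            best[key] = (f, order_i, x)
    unique = sorted(best.values(), key=lambda t: (-t[0], t[1]))
    winners = np.array([x for _, _, x in unique[:top_q]])
    lo, hi = winners.min(axis=0), winners.max(axis=0)
    pad = inflate * (hi - lo)
    lo = np.maximum(space.lower, lo - pad)
    hi = np.minimum(space.upper, hi + pad)
    # keep the box non-degenerate for integer-only survivors
    width = np.maximum(hi - lo, 1e-9)
    return SearchSpace(names=space.names, lower=lo, upper=lo + width, integer=space.integer)


def optimize(
    objective: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: PSOConfig | None = None,
    prefilter: bool = False,
    prefilter_objective: Callable[[np.ndarray, float], float] | None = None,
    max_resource: float = 27,
) -> OptimizeResult:
    """Maximize ``objective`` over ``space``; returns gbest and its trace.

    With ``prefilter=True`` a Hyperband pass narrows the box first (using
    ``prefilter_objective(x, resource)`` or the main objective with resource
    ignored).  The gbest fitness trace is non-decreasing by construction;
    ties keep the earlier particle.
    """
    config = config or PSOConfig()
    search = space
    if prefilter:
        pf = prefilter_objective or (lambda x, _r: objective(x))
        search = hyperband_prefilter(space, pf, max_resource=max_resource, seed=config.seed)

    rng = np.random.default_rng(config.seed)
    n = config.swarm_size
    positions = search.sample(rng, n)
    velocities = rng.uniform(
        -(search.upper - search.lower) / 2, (search.upper - search.lower) / 2, size=(n, search.ndim)
    )
    fitness = np.array([objective(search.round(x)) for x in positions])
    evaluations = n
    best = int(np.argmax(fitness))
    swarm = Swarm(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_fitness=fitness.copy(),
        gbest_position=positions[best].copy(),
        gbest_fitness=float(fitness[best]),
    )

    trace: list[float] = []
    for t in range(config.iterations):
        w = inertia_schedule(t, config.iterations, config.inertia_start, config.inertia_end)
        pso_update(swarm, search, w, config.c1, config.c2, rng)
        fitness = np.array([objective(search.round(x)) for x in swarm.positions])
        evaluations += n
        improved = fitness > swarm.pbest_fitness
        swarm.pbest_positions[improved] = swarm.positions[improved]
        swarm.pbest_fitness[improved] = fitness[improved]
        best = int(np.argmax(swarm.pbest_fitness))
        if swarm.pbest_fitness[best] > swarm.gbest_fitness:
            swarm.gbest_fitness = float(swarm.pbest_fitness[best])
            swarm.gbest_position = swarm.pbest_positions[best].copy()
        trace.append(swarm.gbest_fitness)

    return OptimizeResult(
        best_position=search.round(swarm.gbest_position),
        best_fitness=swarm.gbest_fitness,
        trace=trace,
        evaluations=evaluations,
        narrowed_space=search if prefilter else None,
    )
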