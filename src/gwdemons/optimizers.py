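"""Population metaheuristics over box-bounded search spaces.

The grey-wolf optimizer (GWO) is the primary algorithm: the three best
solutions found so far (alpha, beta, delta) steer the rest of the pack
through encircling-style position updates whose aggressiveness is controlled
by a coefficient ``a`` decaying linearly from 2 to 0 over the run.  For each
wolf W and each leader L:

    A = 2*a*r1 - a,   C = 2*r2          (r1, r2 ~ U[0,1), fresh per use)
    D_L = |C * W_L - W|
    W_L' = W_L - A * D_L

and the wolf's next position is the mean of the three leader-guided
candidates, clamped to the box.  Leaders are replaced only on strict fitness
improvement, and the interface is maximization-native.

Integer-kind dimensions evolve continuously and are rounded to the nearest
integer only when the objective is evaluated and when positions are
reported, which preserves the search dynamics while matching integer
parameter grids.

A registry (:func:`make_optimizer`) exposes the same run contract for
optional comparator algorithms; a standard global-best particle swarm
optimizer is included.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError, EvaluationError

__all__ = [
    "SearchSpace",
    "OptimizerRun",
    "gwo_optimize",
    "pso_optimize",
    "make_optimizer",
    "available_optimizers",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchSpace:
    """Box-bounded search space with per-dimension integer/continuous kinds."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        lo = tuple(float(x) for x in self.lower)
        hi = tuple(float(x) for x in self.upper)
        kinds = tuple(self.kinds)
        if not (len(lo) == len(hi) == len(kinds)) or len(lo) == 0:
            raise ConfigError("lower, upper and kinds must have equal nonzero length")
        for i, (a, b, k) in enumerate(zip(lo, hi, kinds)):
            # equality allowed: a collapsed dimension pins that parameter
            if a > b:
                raise ConfigError(f"dimension {i}: lower {a} must be <= upper {b}")
            if k not in ("integer", "continuous"):
                raise ConfigError(f"dimension {i}: unknown kind {k!r}")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        object.__setattr__(self, "kinds", kinds)

    @property
    def dim(self) -> int:
        return len(self.lower)

    def clamp(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, np.asarray(self.lower), np.asarray(self.upper))

    def quantize(self, position: np.ndarray) -> np.ndarray:
        """Round integer dimensions; the representation handed to objectives."""
        q = np.array(position, dtype=np.float64)
        for i, k in enumerate(self.kinds):
            if k == "integer":
                q[i] = np.rint(q[i])
        return self.clamp(q)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return lo + rng.random((n, self.dim)) * (hi - lo)


@dataclass(frozen=True)
class OptimizerRun:
    """Result of one optimizer run (maximization)."""

    best_position: np.ndarray
    best_fitness: float
    history: tuple[float, ...]
    n_evaluations: int

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "best_position", np.array(self.best_position, dtype=np.float64)
        )


def _evaluate(objective: Objective, space: SearchSpace, position: np.ndarray) -> float:
    q = space.quantize(position)
    value = float(objective(q))
    if not np.isfinite(value):
        raise EvaluationError(f"objective returned {value!r} at position {q.tolist()}")
    return value


def gwo_optimize(
    objective: Objective,
    space: SearchSpace,
    n_pop: int = 15,
    n_iter: int = 20,
    seed: int = 0,
    init_positions: Sequence[Sequence[float]] | None = None,
) -> OptimizerRun:
    """Maximize ``objective`` over ``space`` with the grey-wolf optimizer.

    ``init_positions`` optionally pins the first rows of the initial
    population to given points (clamped to the box) — useful for guaranteeing
    that a known baseline is among the evaluated candidates.  The run is
    fully determined by ``seed``.
    """
    if n_pop < 4:
        raise ConfigError(f"GWO needs n_pop >= 4 (three leaders + pack), got {n_pop}")
    if n_iter < 1:
        raise ConfigError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(seed)
    positions = space.sample(rng, n_pop)
    if init_positions is not None:
        pinned = np.atleast_2d(np.asarray(init_positions, dtype=np.float64))
        if pinned.shape[1] != space.dim:
            raise ConfigError(
                f"init_positions dimension {pinned.shape[1]} != space dimension {space.dim}"
            )
        if pinned.shape[0] > n_pop:
            raise ConfigError("more pinned positions than population slots")
        positions[: pinned.shape[0]] = space.clamp(pinned)

    fitness = np.array([_evaluate(objective, space, p) for p in positions])
    n_evals = n_pop

    order = np.argsort(fitness)[::-1]
    leaders = positions[order[:3]].copy()
    leader_fit = fitness[order[:3]].copy()

    history = [float(leader_fit[0])]
    for t in range(n_iter):
        a = 2.0 * (1.0 - t / n_iter)
        for i in range(n_pop):
            candidate = np.zeros(space.dim)
            for lead in leaders:
                r1 = rng.random(space.dim)
                r2 = rng.random(space.dim)
                A = 2.0 * a * r1 - a
                C = 2.0 * r2
                D = np.abs(C * lead - positions[i])
                candidate += lead - A * D
            positions[i] = space.clamp(candidate / 3.0)
            fitness[i] = _evaluate(objective, space, positions[i])
        n_evals += n_pop
        # strict-improvement leader update keeps incumbents on ties
        for i in range(n_pop):
            if fitness[i] > leader_fit[0]:
                leaders[2], leader_fit[2] = leaders[1], leader_fit[1]
                leaders[1], leader_fit[1] = leaders[0], leader_fit[0]
                leaders[0], leader_fit[0] = positions[i].copy(), fitness[i]
            elif fitness[i] > leader_fit[1]:
                leaders[2], leader_fit[2] = leaders[1], leader_fit[1]
                leaders[1], leader_fit[1] = positions[i].copy(), fitness[i]
            elif fitness[i] > leader_fit[2]:
                leaders[2], leader_fit[2] = positions[i].copy(), fitness[i]
        history.append(float(leader_fit[0]))

    return OptimizerRun(
        best_position=space.quantize(leaders[0]),
        best_fitness=float(leader_fit[0]),
        history=tuple(history),
        n_evaluations=n_evals,
    )


def pso_optimize(
    objective: Objective,
    space: SearchSpace,
    n_pop: int = 15,
    n_iter: int = 20,
    seed: int = 0,
    init_positions: Sequence[Sequence[float]] | None = None,
    inertia: float = 0.72,
    c_personal: float = 1.49,
    c_global: float = 1.49,
) -> OptimizerRun:
    """Standard global-best particle swarm optimizer (maximization).

    Included as an optional comparator; constriction-style coefficients
    (Clerc's w = 0.72, c1 = c2 = 1.49) by default.
    """
    if n_pop < 2:
        raise ConfigError(f"PSO needs n_pop >= 2, got {n_pop}")
    if n_iter < 1:
        raise ConfigError(f"n_iter must be >= 1, got {n_iter}")
    rng = np.random.default_rng(seed)
    lo = np.asarray(space.lower)
    hi = np.asarray(space.upper)
    positions = space.sample(rng, n_pop)
    if init_positions is not None:
        pinned = np.atleast_2d(np.asarray(init_positions, dtype=np.float64))
        if pinned.shape[0] > n_pop or pinned.shape[1] != space.dim:
            raise ConfigError("init_positions incompatible with population/space")
        positions[: pinned.shape[0]] = space.clamp(pinned)
    velocities = (rng.random((n_pop, space.dim)) - 0.5) * (hi - lo) * 0.1

    fitness = np.array([_evaluate(objective, space, p) for p in positions])
    n_evals = n_pop
    pbest = positions.copy()
    pbest_fit = fitness.copy()
    g = int(np.argmax(pbest_fit))
    gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])

    history = [gbest_fit]
    for _ in range(n_iter):
        r1 = rng.random((n_pop, space.dim))
        r2 = rng.random((n_pop, space.dim))
        velocities = (
            inertia * velocities
            + c_personal * r1 * (pbest - positions)
            + c_global * r2 * (gbest - positions)
        )
        positions = space.clamp(positions + velocities)
        fitness = np.array([_evaluate(objective, space, p) for p in positions])
        n_evals += n_pop
        improved = fitness > pbest_fit
        pbest[improved] = positions[improved]
        pbest_fit[improved] = fitness[improved]
        g = int(np.argmax(pbest_fit))
        if pbest_fit[g] > gbest_fit:
            gbest, gbest_fit = pbest[g].copy(), float(pbest_fit[g])
        history.append(gbest_fit)

    return OptimizerRun(
        best_position=space.quantize(gbest),
        best_fitness=gbest_fit,
        history=tuple(history),
        n_evaluations=n_evals,
    )


_REGISTRY: dict[str, Callable[..., OptimizerRun]] = {
    "gwo": gwo_optimize,
    "pso": pso_optimize,
}


def available_optimizers() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def make_optimizer(name: str) -> Callable[..., OptimizerRun]:
    """Look up an optimizer by name; all share the ``gwo_optimize`` contract."""
    try:
        return _REGISTRY[name.lower()]
    except KeyError:
        raise ConfigError(
            f"unknown optimizer {name!r}; available: {', '.join(available_optimizers())}"
        ) from None
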