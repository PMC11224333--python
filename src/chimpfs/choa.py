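"""Baseline chimp optimizer (CHoA) over a bounded continuous search space.

Four leader roles — attacker, barrier, chaser, driver (the four
best-fitness individuals) — guide every candidate. Each generation an
individual either moves to the mean of the four leader-guided targets or
is relocated chaotically within the bounds, with equal probability.

The module also hosts the population/search-space containers and the
optimizer driver contract shared with :mod:`chimpfs.soschoa`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chaos import SineChaosState

__all__ = [
    "SearchSpace",
    "ChimpPopulation",
    "LeaderSet",
    "OptimizeResult",
    "compute_f",
    "sample_coefficients",
    "select_leaders",
    "leader_guided_position",
    "aggregate_position",
    "stochastic_position_update",
    "choa_step",
    "optimize",
    "F_MAX",
]

#: Initial value of the convergence factor; it decays to 0 over the run.
F_MAX = 2.5


@dataclass
class SearchSpace:
    """Axis-aligned box the candidate positions live in."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper shapes differ")
        if np.any(self.lower >= self.upper):
            raise ValueError("lower must be strictly below upper")

    @classmethod
    def unit(cls, dims: int) -> "SearchSpace":
        return cls(np.zeros(dims), np.ones(dims))

    @property
    def dims(self) -> int:
        return self.lower.size

    def clip(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self.lower, self.upper)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.dims))


@dataclass
class ChimpPopulation:
    """N candidate positions with fitnesses and an iteration counter."""

    positions: np.ndarray
    fitnesses: np.ndarray
    iteration: int = 0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.fitnesses = np.asarray(self.fitnesses, dtype=float)
        if self.positions.ndim != 2:
            raise ValueError("positions must be an N x D matrix")
        if self.fitnesses.shape != (self.positions.shape[0],):
            raise ValueError("one fitness per individual required")

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    @property
    def dims(self) -> int:
        return self.positions.shape[1]


@dataclass
class LeaderSet:
    """The four best individuals, ordered best-first."""

    positions: np.ndarray  # 4 x D
    fitnesses: np.ndarray  # length 4
    indices: np.ndarray  # length 4, into the population

    @property
    def attacker(self) -> np.ndarray:
        return self.positions[0]

    @property
    def barrier(self) -> np.ndarray:
        return self.positions[1]

    @property
    def chaser(self) -> np.ndarray:
        return self.positions[2]

    @property
    def driver(self) -> np.ndarray:
        return self.positions[3]


def compute_f(t: int, t_max: int) -> float:
    """Convergence factor, decaying affinely from 2.5 at t=0 to 0 at t=t_max."""
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if not 0 <= t <= t_max:
        raise ValueError("t must lie in [0, t_max]")
    return F_MAX - F_MAX * t / t_max


def sample_coefficients(f: float, rng: np.random.Generator, chaos: SineChaosState,
                        shape=(4,)):
    """Draw the (a, C, m) coefficient triple for each leader.

    ``a = 2 f r1 - f`` lies in [-f, f]; ``C = 2 r2`` lies in [0, 2];
    ``m`` is the next chaotic value in [0, 1]. ``chaos.state`` must have
    the requested shape so each slot has its own stream.
    """
    if not 0.0 <= f <= F_MAX:
        raise ValueError(f"f must lie in [0, {F_MAX}]")
    r1 = rng.uniform(size=shape)
    r2 = rng.uniform(size=shape)
    a = 2.0 * f * r1 - f
    c = 2.0 * r2
    m = chaos.chaotic_value()
    return a, c, m


def select_leaders(pop: ChimpPopulation) -> LeaderSet:
    """Pick the four lowest-fitness individuals; ties broken by index."""
    if pop.size < 4:
        raise ValueError("population must have at least 4 individuals")
    order = np.argsort(pop.fitnesses, kind="stable")[:4]
    return LeaderSet(
        positions=pop.positions[order].copy(),
        fitnesses=pop.fitnesses[order].copy(),
        indices=order,
    )


def leader_guided_position(x, leader, a, c, m):
    """One leader-guided target: ``leader - a * |C * leader - m * x|``."""
    x = np.asarray(x, dtype=float)
    leader = np.asarray(leader, dtype=float)
    if x.shape != leader.shape:
        raise ValueError("position/leader dimension mismatch")
    return leader - a * np.abs(c * leader - m * x)


def aggregate_position(x1, x2, x3, x4):
    """Element-wise mean of the four leader-guided targets."""
    arrs = [np.asarray(v, dtype=float) for v in (x1, x2, x3, x4)]
    if any(v.shape != arrs[0].shape for v in arrs[1:]):
        raise ValueError("dimension mismatch between targets")
    return (arrs[0] + arrs[1] + arrs[2] + arrs[3]) / 4.0


def stochastic_position_update(x, leaders: LeaderSet, coeffs, u: float,
                               chaos_values, space: SearchSpace):
    """Update one position: leader aggregate if u < 0.5, else chaotic jump.

    ``coeffs`` is the (a, C, m) triple for the four leaders (each length
    4); ``chaos_values`` is a length-D vector of chaotic values in [0, 1]
    used for the relocation branch. The result is clamped into bounds.
    """
    if not 0.0 <= u <= 1.0:
        raise ValueError("u must lie in [0, 1]")
    if u < 0.5:
        a, c, m = coeffs
        targets = [
            leader_guided_position(x, leaders.positions[k], a[k], c[k], m[k])
            for k in range(4)
        ]
        new = aggregate_position(*targets)
    else:
        chaos_values = np.asarray(chaos_values, dtype=float)
        new = space.lower + (space.upper - space.lower) * chaos_values
    return space.clip(new)


class CountingObjective:
    """Wraps an objective, counting evaluations and rejecting non-finite values."""

    def __init__(self, objective):
        self._objective = objective
        self.n_evals = 0

    def __call__(self, position, index=None):
        self.n_evals += 1
        value = float(self._objective(position))
        if not np.isfinite(value):
            where = "" if index is None else f" for individual {index}"
            raise ValueError(f"objective returned non-finite value{where}")
        return value

    def evaluate_all(self, positions):
        return np.array([self(p, i) for i, p in enumerate(positions)])


def choa_step(pop: ChimpPopulation, objective, space: SearchSpace, t: int,
              t_max: int, rng: np.random.Generator,
              coef_chaos: SineChaosState, dim_chaos: SineChaosState
              ) -> ChimpPopulation:
    """One CHoA generation: refresh coefficients, move, clamp, re-evaluate.

    ``coef_chaos`` must have state shape (N, 4) (the m coefficients) and
    ``dim_chaos`` shape (N, D) (the chaotic relocation values). Both are
    advanced exactly once per generation regardless of branch outcomes so
    the trajectory is reproducible.
    """
    n, d = pop.positions.shape
    f = compute_f(t, t_max)
    leaders = select_leaders(pop)
    u = rng.uniform(size=n)
    r1 = rng.uniform(size=(n, 4))
    r2 = rng.uniform(size=(n, 4))
    a = 2.0 * f * r1 - f
    c = 2.0 * r2
    m = coef_chaos.chaotic_value()  # (N, 4)
    dim_vals = dim_chaos.chaotic_value()  # (N, D)

    new_positions = np.empty_like(pop.positions)
    for i in range(n):
        new_positions[i] = stochastic_position_update(
            pop.positions[i], leaders, (a[i], c[i], m[i]), u[i],
            dim_vals[i], space)

    if not isinstance(objective, CountingObjective):
        objective = CountingObjective(objective)
    fitnesses = objective.evaluate_all(new_positions)
    return ChimpPopulation(new_positions, fitnesses, iteration=t + 1)


@dataclass
class OptimizeResult:
    """Outcome of a full optimizer run (shared by CHoA and SOSCHoA)."""

    best_position: np.ndarray
    best_fitness: float
    best_curve: np.ndarray  # length t_max + 1, elitist, non-increasing
    diversity_curve: np.ndarray  # length t_max + 1
    evals_per_gen: np.ndarray  # length t_max
    coord_updates_per_gen: np.ndarray  # length t_max
    population: ChimpPopulation = field(repr=False, default=None)


def population_spread(positions: np.ndarray) -> float:
    """Mean Euclidean distance of individuals to the population centroid."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    centroid = positions.mean(axis=0)
    return float(np.linalg.norm(positions - centroid, axis=1).mean())


def optimize(objective, space: SearchSpace, n_individuals: int = 10,
             t_max: int = 100, seed=None) -> OptimizeResult:
    """Run CHoA for ``t_max`` generations and return the elitist best."""
    if n_individuals < 4:
        raise ValueError("population must have at least 4 individuals")
    if t_max < 0:
        raise ValueError("t_max must be >= 0")
    rng = np.random.default_rng(seed)
    counting = objective if isinstance(objective, CountingObjective) \
        else CountingObjective(objective)

    positions = space.sample(rng, n_individuals)
    coef_chaos = SineChaosState.from_rng(rng, (n_individuals, 4))
    dim_chaos = SineChaosState.from_rng(rng, (n_individuals, space.dims))
    fitnesses = counting.evaluate_all(positions)
    pop = ChimpPopulation(positions, fitnesses, iteration=0)

    best_idx = int(np.argmin(pop.fitnesses))
    best_position = pop.positions[best_idx].copy()
    best_fitness = float(pop.fitnesses[best_idx])
    best_curve = [best_fitness]
    diversity_curve = [population_spread(pop.positions)]
    evals_per_gen, coords_per_gen = [], []

    for t in range(t_max):
        evals_before = counting.n_evals
        pop = choa_step(pop, counting, space, t, t_max, rng,
                        coef_chaos, dim_chaos)
        idx = int(np.argmin(pop.fitnesses))
        if pop.fitnesses[idx] < best_fitness:
            best_fitness = float(pop.fitnesses[idx])
            best_position = pop.positions[idx].copy()
        best_curve.append(best_fitness)
        diversity_curve.append(population_spread(pop.positions))
        evals_per_gen.append(counting.n_evals - evals_before)
        coords_per_gen.append(n_individuals * space.dims)

    return OptimizeResult(
        best_position=best_position,
        best_fitness=best_fitness,
        best_curve=np.asarray(best_curve),
        diversity_curve=np.asarray(diversity_curve),
        evals_per_gen=np.asarray(evals_per_gen, dtype=int),
        coord_updates_per_gen=np.asarray(coords_per_gen, dtype=int),
        population=pop,
    )
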