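"""SOSCHoA: chimp optimizer with social coevolution and sine-chaotic opposition.

Two operators distinguish this optimizer from the baseline in
:mod:`chimpfs.choa`:

* a social-coevolution position update that pulls each individual toward
  the attacker relative to the midpoint of itself and its ring
  predecessor, scaled by a benefit factor R in {1, 2}; it is applied on
  top of the baseline leader-aggregate/chaotic-jump move (the baseline
  framework is kept, the social term sharpens it), and
* a dimension-wise sine-chaotic opposition sweep inside dynamic
  (population min/max) bounds, with greedy replacement so no individual's
  fitness ever worsens during the sweep.

Each generation costs exactly 2N objective evaluations: one per
individual after the combined move, one per opposition candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chaos import OppositionBounds, SineChaosState, greedy_select, \
    sine_opposition_point
from .choa import ChimpPopulation, CountingObjective, OptimizeResult, \
    SearchSpace, compute_f, population_spread, select_leaders, \
    stochastic_position_update

__all__ = [
    "SoschoaConfig",
    "ChaosStreams",
    "social_coevolution_update",
    "dynamic_bounds",
    "sine_opposition_sweep",
    "soschoa_step",
    "optimize",
]

OPPOSITION_MODES = ("per-individual", "best-only")


@dataclass
class SoschoaConfig:
    """Run configuration; defaults follow the reference protocol."""

    n_individuals: int = 10
    t_max: int = 100
    seed: object = None
    opposition_mode: str = "per-individual"
    chaos_control: float = 1.0

    def __post_init__(self):
        if self.n_individuals < 4:
            raise ValueError("population must have at least 4 individuals")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")
        if self.opposition_mode not in OPPOSITION_MODES:
            raise ValueError(
                f"opposition_mode must be one of {OPPOSITION_MODES}")
        if not (0.0 < self.chaos_control <= 1.0):
            raise ValueError("chaos_control must lie in (0, 1]")


def social_coevolution_update(x_i, x_prev, attacker, r3: float,
                              benefit: int):
    """Move ``x_i`` toward the attacker relative to the pair midpoint.

    Returns ``x_i + r3 * (attacker - ((x_i + x_prev) / 2) * benefit)``.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_prev = np.asarray(x_prev, dtype=float)
    attacker = np.asarray(attacker, dtype=float)
    if x_i.shape != x_prev.shape or x_i.shape != attacker.shape:
        raise ValueError("position dimension mismatch")
    if not 0.0 <= r3 <= 1.0:
        raise ValueError("r3 must lie in [0, 1]")
    if benefit not in (1, 2):
        raise ValueError("benefit factor must be 1 or 2")
    co_occurrence = (x_i + x_prev) / 2.0
    return x_i + r3 * (attacker - co_occurrence * benefit)


def dynamic_bounds(pop: ChimpPopulation) -> OppositionBounds:
    """Per-dimension min/max of the current population."""
    if pop.size < 1:
        raise ValueError("population is empty")
    return OppositionBounds(lower=pop.positions.min(axis=0),
                            upper=pop.positions.max(axis=0))


def sine_opposition_sweep(pop: ChimpPopulation, objective,
                          bounds: OppositionBounds, chaos: SineChaosState,
                          indices=None) -> ChimpPopulation:
    """Greedy dimension-wise sine-opposition pass over the population.

    For each targeted individual a candidate is built coordinate-wise as
    ``lb_j + (ub_j - x_j) * s_j`` with ``s_j`` the next chaotic value of
    that individual's stream, then kept iff its fitness is no worse.
    ``chaos.state`` must have shape (N, D); the whole stream advances one
    step per sweep so trajectories stay reproducible.
    """
    if not isinstance(objective, CountingObjective):
        objective = CountingObjective(objective)
    if indices is None:
        indices = range(pop.size)
    s = chaos.chaotic_value()  # (N, D)
    positions = pop.positions.copy()
    fitnesses = pop.fitnesses.copy()
    for i in indices:
        candidate = sine_opposition_point(
            positions[i], bounds.lower, bounds.upper, s[i])
        candidate_fitness = objective(candidate, index=i)
        if greedy_select(fitnesses[i], candidate_fitness):
            positions[i] = candidate
            fitnesses[i] = candidate_fitness
    return ChimpPopulation(positions, fitnesses, iteration=pop.iteration)


@dataclass
class ChaosStreams:
    """The three chaotic streams one SOSCHoA run consumes.

    ``coef`` has state shape (N, 4) and feeds the m coefficients;
    ``reloc`` and ``opposition`` have state shape (N, D) and feed the
    chaotic-relocation branch and the opposition modulation.
    """

    coef: SineChaosState
    reloc: SineChaosState
    opposition: SineChaosState

    @classmethod
    def from_rng(cls, rng: np.random.Generator, n: int, d: int,
                 control: float = 1.0):
        return cls(coef=SineChaosState.from_rng(rng, (n, 4)),
                   reloc=SineChaosState.from_rng(rng, (n, d)),
                   opposition=SineChaosState.from_rng(rng, (n, d),
                                                      control=control))


def soschoa_step(pop: ChimpPopulation, objective, space: SearchSpace,
                 t: int, config: SoschoaConfig, rng: np.random.Generator,
                 chaos: ChaosStreams) -> ChimpPopulation:
    """One SOSCHoA generation.

    The baseline leader-aggregate/chaotic-jump move produces an
    intermediate position; the social-coevolution term (ring predecessor
    as the partner, benefit factor drawn per individual) is applied on
    top of it; the combined move is clamped and evaluated once per
    individual. A greedy sine-opposition sweep inside the dynamic
    population bounds then closes the generation.
    """
    n, d = pop.positions.shape
    f = compute_f(t, max(config.t_max, 1))
    leaders = select_leaders(pop)
    u = rng.uniform(size=n)
    r1 = rng.uniform(size=(n, 4))
    r2 = rng.uniform(size=(n, 4))
    a = 2.0 * f * r1 - f
    c = 2.0 * r2
    m = chaos.coef.chaotic_value()  # (N, 4)
    reloc_vals = chaos.reloc.chaotic_value()  # (N, D)

    intermediate = np.empty_like(pop.positions)
    for i in range(n):
        intermediate[i] = stochastic_position_update(
            pop.positions[i], leaders, (a[i], c[i], m[i]), u[i],
            reloc_vals[i], space)

    r3 = rng.uniform(size=n)
    benefit = rng.integers(1, 3, size=n)
    prev = np.roll(intermediate, 1, axis=0)  # partner = ring predecessor
    new_positions = np.empty_like(intermediate)
    for i in range(n):
        new_positions[i] = social_coevolution_update(
            intermediate[i], prev[i], leaders.attacker,
            r3[i], int(benefit[i]))
    new_positions = space.clip(new_positions)

    if not isinstance(objective, CountingObjective):
        objective = CountingObjective(objective)
    fitnesses = objective.evaluate_all(new_positions)
    pop = ChimpPopulation(new_positions, fitnesses, iteration=t + 1)

    bounds = dynamic_bounds(pop)
    if config.opposition_mode == "best-only":
        targets = [int(np.argmin(pop.fitnesses))]
    else:
        targets = None
    return sine_opposition_sweep(pop, objective, bounds, chaos.opposition,
                                 indices=targets)


def optimize(objective, space: SearchSpace,
             config: SoschoaConfig | None = None, **kwargs) -> OptimizeResult:
    """Run SOSCHoA for ``config.t_max`` generations, elitist best tracked.

    Extra keyword arguments are forwarded to :class:`SoschoaConfig` when
    no config object is given.
    """
    if config is None:
        config = SoschoaConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config object or keyword arguments")
    rng = np.random.default_rng(config.seed)
    counting = objective if isinstance(objective, CountingObjective) \
        else CountingObjective(objective)

    n, d = config.n_individuals, space.dims
    positions = space.sample(rng, n)
    chaos = ChaosStreams.from_rng(rng, n, d, control=config.chaos_control)
    fitnesses = counting.evaluate_all(positions)
    pop = ChimpPopulation(positions, fitnesses, iteration=0)

    best_idx = int(np.argmin(pop.fitnesses))
    best_position = pop.positions[best_idx].copy()
    best_fitness = float(pop.fitnesses[best_idx])
    best_curve = [best_fitness]
    diversity_curve = [population_spread(pop.positions)]
    evals_per_gen, coords_per_gen = [], []

    for t in range(config.t_max):
        evals_before = counting.n_evals
        pop = soschoa_step(pop, counting, space, t, config, rng, chaos)
        idx = int(np.argmin(pop.fitnesses))
        if pop.fitnesses[idx] < best_fitness:
            best_fitness = float(pop.fitnesses[idx])
            best_position = pop.positions[idx].copy()
        best_curve.append(best_fitness)
        diversity_curve.append(population_spread(pop.positions))
        evals_per_gen.append(counting.n_evals - evals_before)
        # baseline move + social term + opposition candidates, D coords each
        coords_per_gen.append(3 * n * d)

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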