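"""Repeated-run evaluation statistics, diversity, and rank-sum comparisons.

The run summary follows the reference protocol verbatim: the "SD"
quantities are mean squared deviations (divided by M, no square root);
conventional square-rooted values are emitted alongside under separate
names.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .choa import population_spread
from .feature_selection import FitnessConfig, LabeledDataset, \
    run_feature_selection, split_dataset

__all__ = [
    "RunRecord",
    "RunSummary",
    "ProtocolConfig",
    "ExperimentResult",
    "summarize_runs",
    "diversity",
    "wilcoxon_rank_sum",
    "run_experiment",
]


@dataclass
class RunRecord:
    """Per-run outcome of one optimizer on one dataset split."""

    accuracy: float
    n_selected: int
    fitness: float
    best_curve: np.ndarray = field(repr=False, default=None)
    diversity_curve: np.ndarray = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)
    seed: object = None
    optimizer: str = ""


@dataclass
class RunSummary:
    """Aggregate statistics over M runs."""

    n_runs: int
    acc_mean: float
    acc_max: float
    acc_min: float
    acc_sd: float  # mean squared deviation (divided by M, no sqrt)
    acc_sd_conventional: float  # sqrt of acc_sd
    num_mean: float
    fit_mean: float
    fit_sd: float
    fit_sd_conventional: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _msd(values: np.ndarray) -> float:
    """Mean squared deviation from the mean (division by M, no sqrt)."""
    values = np.asarray(values, dtype=float)
    return float(np.mean((values - values.mean()) ** 2))


def summarize_runs(records: list[RunRecord]) -> RunSummary:
    if not records:
        raise ValueError("need at least one run record")
    acc = np.array([r.accuracy for r in records], dtype=float)
    num = np.array([r.n_selected for r in records], dtype=float)
    fit = np.array([r.fitness for r in records], dtype=float)
    return RunSummary(
        n_runs=len(records),
        acc_mean=float(acc.mean()),
        acc_max=float(acc.max()),
        acc_min=float(acc.min()),
        acc_sd=_msd(acc),
        acc_sd_conventional=float(np.sqrt(_msd(acc))),
        num_mean=float(num.mean()),
        fit_mean=float(fit.mean()),
        fit_sd=_msd(fit),
        fit_sd_conventional=float(np.sqrt(_msd(fit))),
    )


def diversity(pop) -> float:
    """Mean Euclidean distance of individuals to the population centroid.

    Accepts a population object with a ``positions`` attribute or a bare
    N x D array; returns 0 iff the population has collapsed to a point.
    """
    positions = getattr(pop, "positions", pop)
    return population_spread(positions)


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided rank-sum p-value between two samples.

    Exact enumeration (via the Mann-Whitney statistic) for combined
    n <= 20 without ties; otherwise the normal approximation with tie
    correction. Two identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if np.ptp(combined) == 0:
        return 1.0  # no rank separation at all
    if not has_ties and combined.size <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))


@dataclass
class ProtocolConfig:
    """Repeated-run experimental protocol (defaults = reference settings)."""

    n_runs: int = 30
    n_individuals: int = 10
    t_max: int = 100
    alpha: float = 0.99
    k: int = 5
    train_fraction: float = 0.7
    seed: int = 0
    opposition_mode: str = "per-individual"

    def __post_init__(self):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class ExperimentResult:
    records: dict[str, list[RunRecord]]
    summaries: dict[str, RunSummary]
    p_values: dict[tuple[str, str], float]


def run_seed(master_seed: int, run_index: int) -> np.random.SeedSequence:
    """Counter-scheme per-run seed: independent runs, reproducible."""
    return np.random.SeedSequence(entropy=master_seed,
                                  spawn_key=(run_index,))


def run_experiment(dataset: LabeledDataset,
                   optimizers=("choa", "soschoa"),
                   config: ProtocolConfig | None = None) -> ExperimentResult:
    """M seeded runs per optimizer with a fresh split per run.

    Matched optimizers see identical per-run seeds (hence identical
    splits and initial populations), so pairwise rank-sum p-values on
    final fitness compare the update rules, not the draws.
    """
    if config is None:
        config = ProtocolConfig()
    fitness_config = FitnessConfig(alpha=config.alpha, k=config.k)
    records: dict[str, list[RunRecord]] = {name: [] for name in optimizers}

    for i in range(config.n_runs):
        seed_seq = run_seed(config.seed, i)
        split_rng = np.random.default_rng(seed_seq)
        split = split_dataset(dataset, config.train_fraction, split_rng)
        opt_seed = int(np.random.default_rng(run_seed(config.seed, i))
                       .integers(2 ** 31))
        for name in optimizers:
            result = run_feature_selection(
                split, optimizer=name,
                n_individuals=config.n_individuals, t_max=config.t_max,
                seed=opt_seed, fitness_config=fitness_config,
                opposition_mode=config.opposition_mode)
            records[name].append(RunRecord(
                accuracy=result.accuracy,
                n_selected=result.n_selected,
                fitness=result.fitness,
                best_curve=result.best_curve,
                diversity_curve=result.diversity_curve,
                mask=result.mask,
                seed=opt_seed,
                optimizer=name,
            ))

    summaries = {name: summarize_runs(recs) for name, recs in records.items()}
    p_values = {}
    for x, y in itertools.combinations(optimizers, 2):
        fx = [r.fitness for r in records[x]]
        fy = [r.fitness for r in records[y]]
        p_values[(x, y)] = wilcoxon_rank_sum(fx, fy)
    return ExperimentResult(records=records, summaries=summaries,
                            p_values=p_values)
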