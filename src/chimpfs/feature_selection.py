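"""Binary wrapper layer: mask encoding, KNN error, and the selection fitness.

A continuous position in [0, 1]^D is thresholded at 0.5 into a feature
mask; the mask is scored by the misclassification rate of a k-nearest
neighbour classifier fit on the training partition and evaluated on the
held-out partition, combined with the selected-feature fraction:

    fitness = alpha * error + (1 - alpha) * |selected| / |all|

which both optimizers minimize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .choa import SearchSpace

__all__ = [
    "LabeledDataset",
    "FitnessConfig",
    "FeatureSelectionResult",
    "binarize_mask",
    "repair_mask",
    "decode_position",
    "mask_to_string",
    "knn_error_rate",
    "evaluate_fitness",
    "make_objective",
    "split_dataset",
    "run_feature_selection",
]


@dataclass
class LabeledDataset:
    """Sample-by-feature matrix with class labels and an optional split."""

    features: np.ndarray
    labels: np.ndarray
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a samples x D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("one label per sample required")
        if self.train_idx is not None:
            self.train_idx = np.asarray(self.train_idx, dtype=int)
            self.test_idx = np.asarray(self.test_idx, dtype=int)
            combined = np.sort(np.concatenate([self.train_idx, self.test_idx]))
            if not np.array_equal(combined, np.arange(self.n_samples)):
                raise ValueError("partition must be disjoint and exhaustive")
            train_classes = set(np.unique(self.labels[self.train_idx]))
            if set(np.unique(self.labels)) - train_classes:
                raise ValueError("every class needs a training sample")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)

    @property
    def has_partition(self) -> bool:
        return self.train_idx is not None


@dataclass
class FitnessConfig:
    """Weights and classifier settings for the wrapper fitness."""

    alpha: float = 0.99
    k: int = 5

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.k < 1:
            raise ValueError("k must be >= 1")

    @property
    def beta(self) -> float:
        return 1.0 - self.alpha


def binarize_mask(position) -> np.ndarray:
    """Threshold a continuous position at 0.5 into a 0/1 mask.

    Entries exactly at 0.5 map to 1; out-of-range values are handled by
    the comparison itself.
    """
    position = np.asarray(position, dtype=float)
    if not np.all(np.isfinite(position)):
        raise ValueError("position contains non-finite entries")
    return (position >= 0.5).astype(int)


def repair_mask(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Force at least one selected feature; non-empty masks pass through."""
    mask = np.asarray(mask, dtype=int)
    if mask.sum() == 0:
        mask = mask.copy()
        mask[rng.integers(mask.size)] = 1
    return mask


def mask_to_string(mask: np.ndarray) -> str:
    return "".join(str(int(b)) for b in np.asarray(mask, dtype=int))


def _knn_predict(train_x, train_y, test_x, k):
    # Stable argsort: distance ties resolved by lower training index.
    dists = cdist(test_x, train_x)
    neighbours = np.argsort(dists, axis=1, kind="stable")[:, :k]
    votes = train_y[neighbours]
    n_classes = int(train_y.max()) + 1
    preds = np.empty(test_x.shape[0], dtype=int)
    for i, row in enumerate(votes):
        # argmax of bincount: vote ties go to the smallest class label
        preds[i] = int(np.argmax(np.bincount(row, minlength=n_classes)))
    return preds


def knn_error_rate(dataset: LabeledDataset, mask, k: int = 5) -> float:
    """Held-out misclassification rate of KNN on the selected features."""
    mask = np.asarray(mask, dtype=int)
    if mask.sum() == 0:
        raise ValueError("mask selects no features")
    if not dataset.has_partition:
        raise ValueError("dataset has no train/test partition")
    if k > dataset.train_idx.size:
        raise ValueError("k exceeds the training-set size")
    cols = np.flatnonzero(mask)
    train_x = dataset.features[np.ix_(dataset.train_idx, cols)]
    test_x = dataset.features[np.ix_(dataset.test_idx, cols)]
    labels = np.asarray(dataset.labels, dtype=int)
    preds = _knn_predict(train_x, labels[dataset.train_idx], test_x, k)
    return float(np.mean(preds != labels[dataset.test_idx]))


def _position_rng(position, salt: int = 0) -> np.random.Generator:
    """RNG derived from the position bytes, so repair (and hence fitness)
    is a pure function of the position."""
    digest = np.frombuffer(np.ascontiguousarray(position, dtype=float)
                           .tobytes(), dtype=np.uint8)
    return np.random.default_rng([salt, *digest[:64]])


def decode_position(position, salt: int = 0) -> np.ndarray:
    """Binarize a continuous position and repair an empty mask
    deterministically (the repair draw is seeded from the position)."""
    mask = binarize_mask(position)
    return repair_mask(mask, _position_rng(position, salt))


def evaluate_fitness(dataset: LabeledDataset, position,
                     config: FitnessConfig, salt: int = 0) -> float:
    """Wrapper fitness of a continuous position (binarize, repair, score)."""
    mask = decode_position(position, salt)
    error = knn_error_rate(dataset, mask, k=config.k)
    return config.alpha * error + config.beta * mask.mean()


def make_objective(dataset: LabeledDataset, config: FitnessConfig,
                   salt: int = 0):
    """Bind dataset/config into an objective for the continuous optimizers."""

    def objective(position):
        return evaluate_fitness(dataset, position, config, salt)

    return objective


def split_dataset(dataset: LabeledDataset, train_fraction: float,
                  rng: np.random.Generator) -> LabeledDataset:
    """Stratified random train/test partition.

    The overall training size is round(train_fraction * n); per-class
    counts are allocated by largest remainder with every class keeping at
    least one training sample. A single-sample class is forced into
    training with a warning.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    labels = dataset.labels
    classes, counts = np.unique(labels, return_counts=True)
    n = dataset.n_samples
    n_train_total = int(round(train_fraction * n))
    n_train_total = min(max(n_train_total, classes.size), n - 1)

    exact = train_fraction * counts
    base = np.maximum(np.floor(exact).astype(int), 1)
    base = np.minimum(base, counts)
    remainder = exact - base
    while base.sum() < n_train_total:
        room = base < counts
        if not room.any():
            break
        pick = int(np.argmax(np.where(room, remainder, -np.inf)))
        base[pick] += 1
        remainder[pick] -= 1.0
    while base.sum() > n_train_total:
        shrinkable = base > 1
        if not shrinkable.any():
            break
        pick = int(np.argmin(np.where(shrinkable, remainder, np.inf)))
        base[pick] -= 1
        remainder[pick] += 1.0

    train_parts, test_parts = [], []
    for cls, n_c, n_train_c in zip(classes, counts, base):
        idx = np.flatnonzero(labels == cls)
        if n_c == 1:
            warnings.warn(
                f"class {cls!r} has a single sample; forced into training",
                stacklevel=2)
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train_c])
        test_parts.append(perm[n_train_c:])

    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    return LabeledDataset(dataset.features, dataset.labels,
                          train_idx=train_idx, test_idx=test_idx)


@dataclass
class FeatureSelectionResult:
    """Outcome of one wrapper feature-selection run."""

    mask: np.ndarray
    fitness: float
    accuracy: float
    best_curve: np.ndarray = field(repr=False, default=None)
    diversity_curve: np.ndarray = field(repr=False, default=None)

    @property
    def n_selected(self) -> int:
        return int(np.asarray(self.mask).sum())

    @property
    def selected_indices(self) -> list[int]:
        """Selected feature indices, 1-based as in human-facing reports."""
        return [int(j) + 1 for j in np.flatnonzero(self.mask)]

    @property
    def mask_string(self) -> str:
        return mask_to_string(self.mask)


def run_feature_selection(dataset: LabeledDataset, optimizer: str = "soschoa",
                          n_individuals: int = 10, t_max: int = 100,
                          seed=None, fitness_config: FitnessConfig | None = None,
                          opposition_mode: str = "per-individual"
                          ) -> FeatureSelectionResult:
    """Run one optimizer over [0, 1]^D and decode the best mask found."""
    from . import choa, soschoa  # local import avoids a cycle at load time

    if fitness_config is None:
        fitness_config = FitnessConfig()
    if not dataset.has_partition:
        raise ValueError("dataset needs a train/test partition; "
                         "call split_dataset first")
    objective = make_objective(dataset, fitness_config)
    space = SearchSpace.unit(dataset.n_features)

    if optimizer == "soschoa":
        result = soschoa.optimize(
            objective, space,
            soschoa.SoschoaConfig(n_individuals=n_individuals, t_max=t_max,
                                  seed=seed, opposition_mode=opposition_mode))
    elif optimizer == "choa":
        result = choa.optimize(objective, space, n_individuals=n_individuals,
                               t_max=t_max, seed=seed)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    mask = decode_position(result.best_position)
    accuracy = 1.0 - knn_error_rate(dataset, mask, k=fitness_config.k)
    return FeatureSelectionResult(
        mask=mask, fitness=result.best_fitness, accuracy=accuracy,
        best_curve=result.best_curve, diversity_curve=result.diversity_curve)
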