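"""Seeded generator of microarray-like datasets with planted structure.

Few samples, many features: a small set of class-informative Gaussian
features (class means spaced by a separation parameter), optional noisy
copies of informative features, and label-independent Gaussian noise
features. Column order is shuffled and the ground-truth roles recorded,
so feature-recovery experiments need no external downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .feature_selection import LabeledDataset

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "Table2Example",
    "generate_dataset",
    "strong_signal_spec",
    "table2_fixture",
]


@dataclass
class SyntheticSpec:
    """Shape and signal parameters of a generated dataset."""

    n_samples: int = 100
    n_classes: int = 2
    n_informative: int = 10
    n_redundant: int = 10
    n_noise: int = 180
    class_separation: float = 2.0
    redundancy_noise: float = 0.5
    mean_pattern: str = "linear"
    seed: object = None

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("need at least 2 samples per class")
        if self.n_informative < 1:
            raise ValueError("need at least 1 informative feature")
        if self.n_redundant < 0 or self.n_noise < 0:
            raise ValueError("feature counts must be non-negative")
        if self.class_separation <= 0:
            raise ValueError("class_separation must be positive")
        if self.redundancy_noise < 0:
            raise ValueError("redundancy_noise must be non-negative")
        if self.mean_pattern not in ("linear", "indicator"):
            raise ValueError("mean_pattern must be 'linear' or 'indicator'")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


@dataclass
class GroundTruth:
    """Post-shuffle column indices of each planted feature role."""

    informative: np.ndarray
    redundant: np.ndarray
    noise: np.ndarray
    redundant_parent: np.ndarray  # informative column each redundant copies


def generate_dataset(spec: SyntheticSpec) -> tuple[LabeledDataset, GroundTruth]:
    """Generate a labeled dataset plus the planted ground truth.

    Under the default "linear" pattern, informative feature j of a
    class-c sample is N(c * separation, 1): every informative feature
    carries the same class contrast. Under the "indicator" pattern,
    informative feature j has mean ``separation`` for class ``j mod
    n_classes`` and 0 otherwise, so each feature is needed to tell one
    class apart. Redundant features are a random informative column plus
    N(0, redundancy_noise); noise features are N(0, 1).
    """
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features
    labels = rng.permutation(np.arange(n) % spec.n_classes)

    if spec.mean_pattern == "linear":
        means = spec.class_separation * np.tile(
            np.arange(spec.n_classes, dtype=float)[:, None],
            (1, spec.n_informative))
    else:
        feature_class = np.arange(spec.n_informative) % spec.n_classes
        means = spec.class_separation * (
            np.arange(spec.n_classes)[:, None] == feature_class[None, :]
        ).astype(float)
    informative = rng.standard_normal((n, spec.n_informative)) \
        + means[labels]

    parents = rng.integers(spec.n_informative, size=spec.n_redundant)
    redundant = informative[:, parents] \
        + spec.redundancy_noise * rng.standard_normal((n, spec.n_redundant))

    noise = rng.standard_normal((n, spec.n_noise))

    stacked = np.hstack([informative, redundant, noise])
    perm = rng.permutation(d)
    features = stacked[:, perm]

    # column_of[original stacked index] -> shuffled column index
    column_of = np.empty(d, dtype=int)
    column_of[perm] = np.arange(d)
    info_cols = column_of[: spec.n_informative]
    red_cols = column_of[spec.n_informative: spec.n_informative + spec.n_redundant]
    noise_cols = column_of[spec.n_informative + spec.n_redundant:]
    parent_cols = info_cols[parents]

    truth = GroundTruth(informative=info_cols, redundant=red_cols,
                        noise=noise_cols, redundant_parent=parent_cols)
    return LabeledDataset(features, labels), truth


def strong_signal_spec(seed=None) -> SyntheticSpec:
    """Recovery preset (n=100, D=200, 10 planted features).

    Uses the one-vs-rest "indicator" mean pattern with one informative
    feature per class, so dropping any planted feature collapses one
    class into the rest and costs real held-out error — the planted set
    is jointly necessary, not mutually redundant.
    """
    return SyntheticSpec(n_samples=100, n_classes=10, n_informative=10,
                         n_redundant=0, n_noise=190, class_separation=8.0,
                         mean_pattern="indicator", seed=seed)


@dataclass
class Table2Example:
    """The worked 9-feature encoding example."""

    mask_string: str
    mask: np.ndarray
    selected: set[int]  # 1-based
    unselected: set[int]  # 1-based

    @property
    def dimension(self) -> int:
        return len(self.mask_string)


def table2_fixture() -> Table2Example:
    """Worked 9-feature mask example: location string "110100110"."""
    mask_string = "110100110"
    mask = np.array([int(c) for c in mask_string])
    selected = {j + 1 for j in np.flatnonzero(mask)}
    unselected = {j + 1 for j in np.flatnonzero(mask == 0)}
    return Table2Example(mask_string=mask_string, mask=mask,
                         selected=selected, unselected=unselected)
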