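"""Dataset readers and writers: CSV (label column last) and X/Y .mat."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import loadmat, savemat

from .feature_selection import LabeledDataset

__all__ = ["read_dataset", "write_csv", "write_mat"]

logger = logging.getLogger(__name__)


def _encode_labels(raw) -> np.ndarray:
    """Re-encode labels to consecutive integers 0..K-1, logging the map."""
    raw = np.asarray(raw).ravel()
    uniques, encoded = np.unique(raw, return_inverse=True)
    mapping = {str(orig): int(code) for code, orig in enumerate(uniques)}
    logger.info("label encoding: %s", mapping)
    return encoded.astype(int)


def read_dataset(path) -> LabeledDataset:
    """Load a dataset from CSV (last column = label) or a .mat container.

    The .mat layout expects a samples-by-features matrix ``X`` and a
    label vector ``Y``. Labels are re-encoded to consecutive integers.
    """
    path = Path(path)
    if path.suffix.lower() == ".mat":
        contents = loadmat(path)
        for key in ("X", "Y"):
            if key not in contents:
                raise ValueError(f"missing variable {key!r} in {path}")
        x = np.asarray(contents["X"], dtype=float)
        y = np.asarray(contents["Y"]).ravel()
        if x.ndim != 2:
            raise ValueError("X must be a samples x features matrix")
        if y.size != x.shape[0]:
            raise ValueError(
                f"Y length {y.size} does not match X rows {x.shape[0]}")
        return LabeledDataset(x, _encode_labels(y))

    frame = pd.read_csv(path)
    if frame.shape[1] < 2:
        raise ValueError("CSV needs at least one feature column plus labels")
    features = frame.iloc[:, :-1]
    non_numeric = [c for c in features.columns
                   if not np.issubdtype(features[c].dtype, np.number)]
    if non_numeric:
        raise ValueError(f"non-numeric feature columns: {non_numeric}")
    labels = _encode_labels(frame.iloc[:, -1].to_numpy())
    return LabeledDataset(features.to_numpy(dtype=float), labels)


def write_csv(dataset: LabeledDataset, path) -> None:
    """Write features plus a trailing ``label`` column with a header row."""
    frame = pd.DataFrame(
        dataset.features,
        columns=[f"f{j + 1}" for j in range(dataset.n_features)])
    frame["label"] = dataset.labels
    frame.to_csv(path, index=False)


def write_mat(dataset: LabeledDataset, path) -> None:
    """Write the X/Y .mat layout (Y as a column vector)."""
    savemat(path, {"X": dataset.features,
                   "Y": np.asarray(dataset.labels).reshape(-1, 1)})
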