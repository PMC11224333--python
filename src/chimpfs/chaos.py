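"""Sine chaotic map and opposition-learning primitives.

These are the low-level stochastic building blocks shared by the two
optimizers: a sine chaotic map ``x -> a * sin(pi * x)``, classical
opposition (reflection about the interval midpoint), the sine-modulated
opposition candidate, and the greedy keep-the-better rule used to decide
whether an opposition candidate replaces its original.

All functions accept scalars or NumPy arrays and broadcast element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SineChaosState",
    "OppositionBounds",
    "sine_map_step",
    "opposition_point",
    "sine_opposition_point",
    "greedy_select",
]


def sine_map_step(state, control=1.0):
    """Advance the sine chaotic map one step: ``control * sin(pi * state)``.

    Parameters
    ----------
    state : float or ndarray
        Current map state(s), each in ``[0, 1]``.
    control : float
        Map control parameter ``a`` in ``(0, 1]``. With ``control <= 1``
        the iterates never leave ``[0, control]``.

    Returns
    -------
    float or ndarray
        The next iterate(s), in ``[0, control]``.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < 0.0) or np.any(state > 1.0):
        raise ValueError("sine map state must lie in [0, 1]")
    if not (0.0 < control <= 1.0):
        raise ValueError("sine map control parameter must lie in (0, 1]")
    out = control * np.sin(np.pi * state)
    # sin can overshoot by one ulp near the peak; keep the closure exact.
    out = np.clip(out, 0.0, control)
    return float(out) if out.ndim == 0 else out


@dataclass
class SineChaosState:
    """A deterministic stream of sine-map iterates.

    ``state`` may be any shape; every call to :meth:`step` advances all
    components once. The stream is fully determined by ``(control,
    initial state)``.
    """

    state: np.ndarray
    control: float = 1.0
    position: int = 0

    def __post_init__(self):
        self.state = np.asarray(self.state, dtype=float)
        if not (0.0 < self.control <= 1.0):
            raise ValueError("control must lie in (0, 1]")
        if np.any(self.state < 0.0) or np.any(self.state > 1.0):
            raise ValueError("initial state must lie in [0, 1]")

    @classmethod
    def from_rng(cls, rng: np.random.Generator, shape, control: float = 1.0):
        """Seed a stream with initial states uniform on (0.05, 0.95).

        The open margin avoids the map's fixed point at 0 and states that
        iterate onto it.
        """
        init = rng.uniform(0.05, 0.95, size=shape)
        return cls(state=init, control=control)

    def step(self):
        """Advance once and return the raw iterate(s) in ``[0, control]``."""
        self.state = np.asarray(sine_map_step(self.state, self.control))
        self.position += 1
        return self.state.copy()

    def chaotic_value(self):
        """Advance once and return the iterate(s) rescaled to ``[0, 1]``."""
        return self.step() / self.control


@dataclass
class OppositionBounds:
    """Per-dimension interval used to form opposition candidates."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ValueError("lower/upper shapes differ")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bound exceeds upper bound")


def _check_in_interval(x, lower, upper):
    x = np.asarray(x, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if np.any(lower > upper):
        raise ValueError("lower bound exceeds upper bound")
    if np.any(x < lower) or np.any(x > upper):
        raise ValueError("point lies outside [lower, upper]")
    return x, lower, upper


def opposition_point(x, lower, upper):
    """Reflect ``x`` about the midpoint of ``[lower, upper]``.

    Returns ``lower + upper - x``; an involution on the interval.
    """
    x, lower, upper = _check_in_interval(x, lower, upper)
    out = lower + upper - x
    return float(out) if out.ndim == 0 else out


def sine_opposition_point(x, lower, upper, s):
    """Sine-modulated opposition candidate ``lower + (upper - x) * s``.

    With ``s`` in ``[0, 1]`` and ``x`` inside the interval the result is
    guaranteed to stay inside ``[lower, upper]``; when the interval has
    collapsed (``lower == upper``) the candidate equals that point.
    """
    x, lower, upper = _check_in_interval(x, lower, upper)
    s = np.asarray(s, dtype=float)
    if np.any(s < 0.0) or np.any(s > 1.0):
        raise ValueError("s must lie in [0, 1]")
    out = lower + (upper - x) * s
    return float(out) if out.ndim == 0 else out


def greedy_select(original_fitness: float, opposition_fitness: float) -> bool:
    """Return True iff the opposition candidate should replace the original.

    Minimization; ties go to the opposition candidate.
    """
    if not (np.isfinite(original_fitness) and np.isfinite(opposition_fitness)):
        raise ValueError("fitness values must be finite")
    return bool(opposition_fitness <= original_fitness)
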