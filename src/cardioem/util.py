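"""Shared small utilities and exception types."""

from __future__ import annotations

import numpy as np


class CardioemError(Exception):
    """Base class for package errors."""


class InvalidStateError(CardioemError):
    """A model state violates its invariants (non-finite, out of range)."""


class InstabilityError(CardioemError):
    """A numerical step produced an invalid state (instability)."""


class ConfigurationError(CardioemError):
    """Inconsistent or infeasible configuration."""


def check_finite(name_value_pairs) -> None:
    """Raise InvalidStateError naming the first non-finite field."""
    for name, value in name_value_pairs:
        if not np.all(np.isfinite(value)):
            raise InvalidStateError(f"non-finite value in field {name!r}")


def trapezoid_cumulative(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cumulative trapezoidal integral of y(t), starting at 0."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or y.shape[-1] != t.shape[0]:
        raise ValueError("time grid and trace shapes do not match")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time grid must be strictly increasing")
    out = np.zeros_like(y)
    out[..., 1:] = np.cumsum(0.5 * (y[..., 1:] + y[..., :-1]) * np.diff(t), axis=-1)
    return out
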