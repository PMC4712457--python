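"""Time grids and sampled concentration curves.

A :class:`TimeGrid` is a strictly increasing vector of sample times in
seconds; a :class:`TimeSeriesCurve` is a finite-valued curve sampled on such
a grid (signal, blood concentration or plasma concentration -- the values are
in arbitrary concentration units throughout).

Grids need not be uniform: vendor DICOM dialects yield per-frame timestamps
and every downstream algorithm (convolution, fitting) consumes the full time
vector.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridError


@dataclass(frozen=True)
class TimeGrid:
    """Sample times in seconds.

    Parameters
    ----------
    t : array-like
        Nondecreasing, finite sample times. Duplicates are removed. At least
        three distinct samples are required.
    """

    t: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1:
            raise GridError("time vector must be one-dimensional")
        if not np.all(np.isfinite(t)):
            raise GridError("time vector contains non-finite values")
        if np.any(np.diff(t) < 0):
            raise GridError("time vector must be nondecreasing")
        t = np.unique(t)
        if t.size < 3:
            raise GridError("a time grid needs at least 3 distinct samples")
        object.__setattr__(self, "t", t)

    @property
    def n(self) -> int:
        return self.t.size

    @property
    def dt(self) -> np.ndarray:
        """Interval lengths, length n - 1."""
        return np.diff(self.t)

    def rezeroed(self) -> "TimeGrid":
        """Shift so the first sample sits at t = 0."""
        return TimeGrid(self.t - self.t[0])

    @classmethod
    def uniform(cls, n: int, dt: float, t0: float = 0.0) -> "TimeGrid":
        return cls(t0 + dt * np.arange(n, dtype=float))

    def matches(self, other: "TimeGrid") -> bool:
        return self.t.shape == other.t.shape and np.array_equal(self.t, other.t)


@dataclass(frozen=True)
class TimeSeriesCurve:
    """A curve sampled on a :class:`TimeGrid`; values must be finite."""

    grid: TimeGrid
    values: np.ndarray
    label: str = field(default="", compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size != self.grid.n:
            raise GridError(
                f"curve has {v.size} values but its grid has {self.grid.n} samples"
            )
        if not np.all(np.isfinite(v)):
            raise GridError("curve contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def t(self) -> np.ndarray:
        return self.grid.t

    def with_values(self, values, label: str | None = None) -> "TimeSeriesCurve":
        return TimeSeriesCurve(self.grid, values, self.label if label is None else label)


def require_same_grid(a: TimeSeriesCurve, b: TimeSeriesCurve) -> TimeGrid:
    if not a.grid.matches(b.grid):
        raise GridError("curves are sampled on different time grids")
    return a.grid
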