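"""Piecewise-constant step functions of time.

Operating schedules (incident light, feed flow, dilution rate) are
right-open step functions: the value attached to breakpoint ``t_i`` holds on
``[t_i, t_{i+1})``.  Times are in days.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StepFunction:
    """A piecewise-constant function ``t -> value``.

    Parameters
    ----------
    times : tuple of float
        Strictly increasing breakpoints; ``times[0]`` is the start of the
        domain.  Queries before ``times[0]`` return the first value.
    values : tuple of float
        Value on each interval ``[times[i], times[i+1])``; the last value
        extends to infinity.
    """

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) == 0 or len(self.times) != len(self.values):
            raise ValueError("times and values must be non-empty and of equal length")
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("breakpoints must be strictly increasing")

    @classmethod
    def constant(cls, value: float, start: float = 0.0) -> "StepFunction":
        return cls(times=(float(start),), values=(float(value),))

    def __call__(self, t):
        idx = np.searchsorted(np.asarray(self.times), t, side="right") - 1
        idx = np.clip(idx, 0, len(self.values) - 1)
        vals = np.asarray(self.values)[idx]
        return float(vals) if np.isscalar(t) else vals

    @property
    def is_zero(self) -> bool:
        return all(v == 0.0 for v in self.values)

    @property
    def max_value(self) -> float:
        return max(self.values)

    def breakpoints_within(self, t0: float, t1: float) -> list[float]:
        """Breakpoints strictly inside the open interval ``(t0, t1)``."""
        return [t for t in self.times if t0 < t < t1]

    def integral(self, t0: float, t1: float) -> float:
        """Exact integral of the step function over ``[t0, t1]``."""
        if t1 < t0:
            raise ValueError("t1 must be >= t0")
        knots = [t0] + self.breakpoints_within(t0, t1) + [t1]
        return sum(
            self(a) * (b - a) for a, b in zip(knots[:-1], knots[1:])
        )
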