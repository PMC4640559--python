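"""Piecewise-linear time curves.

Measured inputs (the PIP3 time course) and latent non-canonical deviations
are both represented as linear splines: a value is attached to each knot
time, and intermediate times are linearly interpolated.  Knot values are
plain numbers in arbitrary abundance units; knot times are minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: The study's measurement grid, in minutes.  Deviation splines are knotted
#: on this grid, and synthetic datasets are sampled on it.
MEASUREMENT_GRID: tuple[float, ...] = (0.0, 2.0, 5.0, 10.0, 30.0, 60.0, 120.0)


class CurveError(ValueError):
    """Raised for ill-formed spline configurations."""


@dataclass(frozen=True)
class SplineCurve:
    """A piecewise-linear, non-negative function of time.

    Parameters
    ----------
    knot_times
        Strictly increasing times in minutes, length >= 2.
    knot_values
        Non-negative abundances, one per knot time.

    Outside the knot span the curve is clamped to the first/last knot
    value rather than extrapolated, so abundances can never go negative
    through evaluation.
    """

    knot_times: tuple[float, ...]
    knot_values: tuple[float, ...]

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.knot_times)
        values = tuple(float(v) for v in self.knot_values)
        if len(times) < 2:
            raise CurveError("a spline curve needs at least two knots")
        if len(times) != len(values):
            raise CurveError("knot_times and knot_values must have equal length")
        if not all(b > a for a, b in zip(times, times[1:])):
            raise CurveError(f"knot times must be strictly increasing: {times}")
        if any(v < 0 for v in values):
            raise CurveError(f"knot values must be non-negative: {values}")
        object.__setattr__(self, "knot_times", times)
        object.__setattr__(self, "knot_values", values)

    def __call__(self, t):
        """Evaluate the curve at time(s) ``t`` (minutes)."""
        return np.interp(t, self.knot_times, self.knot_values)

    @property
    def span(self) -> tuple[float, float]:
        return self.knot_times[0], self.knot_times[-1]

    @classmethod
    def constant(cls, value: float, span: Sequence[float] = (0.0, 120.0)) -> "SplineCurve":
        """A flat curve at ``value`` over ``span``."""
        return cls((float(span[0]), float(span[-1])), (value, value))

    @classmethod
    def on_grid(cls, values: Iterable[float], grid: Sequence[float] = MEASUREMENT_GRID) -> "SplineCurve":
        """Knot ``values`` on the measurement grid (the default knot layout)."""
        return cls(tuple(grid), tuple(values))

    def with_value(self, time: float, value: float) -> "SplineCurve":
        """Return a copy with the knot at ``time`` replaced by ``value``."""
        if time not in self.knot_times:
            raise CurveError(f"no knot at t={time} (knots at {self.knot_times})")
        i = self.knot_times.index(time)
        values = list(self.knot_values)
        values[i] = value
        return SplineCurve(self.knot_times, tuple(values))

    def scaled(self, factor: float) -> "SplineCurve":
        return SplineCurve(self.knot_times, tuple(v * factor for v in self.knot_values))


def spline_eval(curve: SplineCurve, t):
    """Linear interpolation between the bracketing knots (clamped outside)."""
    return curve(t)
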