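"""ODE integration of a ModelSpec, plus in-silico interventions.

Simulation follows a simple loop: input and deviation curves are evaluated
by spline interpolation at each solver time (they are never integrated),
while the governed species are advanced by a stiff-capable adaptive
integrator (LSODA).  Derived observables are appended columnwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .models import ConfigurationError, ModelSpec, derived_observables, make_rhs
from .splines import MEASUREMENT_GRID, SplineCurve

__all__ = [
    "Trajectory",
    "Intervention",
    "SimulationError",
    "default_grid",
    "simulate",
    "apply_intervention",
    "normalize_trajectory",
]

OBSERVABLES = ("Aktp308", "TotMemAkt", "PDK1m", "Aktp308m", "Aktp308c")


class SimulationError(RuntimeError):
    """The integrator failed or produced a materially negative state."""


class NormalizationError(ValueError):
    pass


def default_grid(t_end: float = 120.0) -> np.ndarray:
    """1-minute output grid over [0, t_end] merged with the measurement grid."""
    grid = np.union1d(np.arange(0.0, t_end + 0.5, 1.0), MEASUREMENT_GRID)
    return grid[grid <= t_end + 1e-9]


@dataclass(frozen=True)
class Trajectory:
    """Simulated species abundances and derived observables on a time grid."""

    times: np.ndarray
    states: pd.DataFrame       # index: time, columns: species
    observables: pd.DataFrame  # index: time, columns: OBSERVABLES
    variant: str

    def observable(self, name: str) -> pd.Series:
        return self.observables[name]

    def species(self, name: str) -> pd.Series:
        return self.states[name]

    def at(self, times: Sequence[float], observable: str) -> np.ndarray:
        """Observable values at arbitrary times (linear interpolation)."""
        return np.interp(times, self.times, self.observables[observable].to_numpy())

    def to_tidy(self, condition: str = "serum") -> pd.DataFrame:
        frames = []
        for source in (self.states, self.observables):
            df = source.reset_index(names="time_min").melt(
                id_vars="time_min", var_name="species", value_name="value"
            )
            frames.append(df)
        tidy = pd.concat(frames, ignore_index=True).drop_duplicates(
            subset=["time_min", "species"]
        )
        tidy["variant"] = self.variant
        tidy["condition"] = condition
        return tidy


def integrate_states(
    spec: ModelSpec,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Raw state matrix (time x species) — the fast path under
    :func:`simulate` and the calibration objective."""
    f = make_rhs(spec)
    y0 = spec.y0()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        y, info = odeint(
            f, y0, times, rtol=rtol, atol=atol, mxstep=20000, full_output=True,
            tcrit=np.asarray(spec.inputs["PIP3"].knot_times),
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
        t_fail = float(info.get("tcur", [times[-1]])[-1])
        raise SimulationError(f"integration failed near t={t_fail:.3g} min")
    if y.min() < -1e-9:
        i, j = np.unravel_index(np.argmin(y), y.shape)
        raise SimulationError(
            f"negative concentration {y[i, j]:.3g} for "
            f"{spec.species[j]} at t={times[i]:.3g} min"
        )
    return np.clip(y, 0.0, None)


def simulate(
    spec: ModelSpec,
    t_out: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate ``spec`` over ``t_out`` (default: dense 0-120 min grid).

    Tiny negative excursions (> -1e-9) are clipped to zero; larger ones, or
    solver failure, raise :class:`SimulationError` carrying the failing
    time.
    """
    times = np.asarray(default_grid() if t_out is None else t_out, dtype=float)
    if times.ndim != 1 or len(times) < 2 or np.any(np.diff(times) <= 0):
        raise ConfigurationError("t_out must be an increasing grid of >= 2 times")
    y = integrate_states(spec, times, rtol, atol)
    states = pd.DataFrame(y, index=pd.Index(times, name="time_min"),
                          columns=list(spec.species))
    obs = derived_observables(y, spec.variant)
    observables = pd.DataFrame(
        {name: obs[name] for name in OBSERVABLES},
        index=states.index,
    )
    return Trajectory(times, states, observables, spec.variant)


@dataclass(frozen=True)
class Intervention:
    """A structural perturbation applied before simulation.

    kinds: ``clamp_input`` (replace the named input spline with a constant
    from ``onset`` onwards), ``scale_deviation`` (multiply the named
    deviation curve), ``replace_initial_state``.
    An onset at or before t=0 means "for the whole simulation".
    """

    kind: str
    target: str
    value: object = None
    onset: float = 0.0


def apply_intervention(spec: ModelSpec, iv: Intervention) -> ModelSpec:
    """Return a new spec with ``iv`` applied; the original is unchanged.

    Deviation curves are retained unless explicitly targeted — the
    serum-induced non-canonical input is maintained under input clamping.
    """
    if iv.kind == "clamp_input":
        if iv.target not in spec.inputs:
            raise ConfigurationError(f"unknown input {iv.target!r}")
        level = float(iv.value)
        if level < 0:
            raise ConfigurationError("clamped inputs must stay >= 0")
        old = spec.inputs[iv.target]
        if iv.onset <= old.knot_times[0]:
            curve = SplineCurve.constant(level, old.span)
        else:
            # keep the measured curve up to onset, hold constant afterwards
            t_on = float(iv.onset)
            times = [t for t in old.knot_times if t < t_on] + [t_on, old.knot_times[-1]]
            values = [old(t) for t in times[:-2]] + [level, level]
            curve = SplineCurve(tuple(times), tuple(values))
        return spec.with_input(iv.target, curve)
    if iv.kind == "scale_deviation":
        if iv.target not in spec.deviations:
            raise ConfigurationError(f"unknown deviation {iv.target!r}")
        return spec.with_deviation(spec.deviations[iv.target].scaled(float(iv.value)))
    if iv.kind == "replace_initial_state":
        return replace(spec, init=iv.value)
    raise ConfigurationError(f"unknown intervention kind {iv.kind!r}")


def apply_interventions(spec: ModelSpec, ivs: Iterable[Intervention]) -> ModelSpec:
    """Compose interventions left-to-right."""
    for iv in ivs:
        spec = apply_intervention(spec, iv)
    return spec


def normalize_trajectory(
    traj: Trajectory,
    anchor_time: float | None = None,
    max_to: float | None = None,
) -> Trajectory:
    """Rescale each observable series so its anchor-time value (or its
    maximum) equals the requested value.  Shape features are unchanged."""
    if (anchor_time is None) == (max_to is None):
        raise NormalizationError("specify exactly one of anchor_time or max_to")
    obs = traj.observables.copy()
    for col in obs.columns:
        series = obs[col].to_numpy()
        if anchor_time is not None:
            anchor = float(np.interp(anchor_time, traj.times, series))
            target = 1.0
        else:
            anchor = float(series.max())
            target = float(max_to)
        if anchor <= 0:
            raise NormalizationError(f"zero anchor for observable {col!r}")
        obs[col] = series * (target / anchor)
    return replace(traj, observables=obs)
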