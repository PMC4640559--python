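"""Weighted-SSE model calibration: multistart PSO + Nelder-Mead.

The objective is the weighted sum of squared residuals between simulated
and observed series (weights n_t / sum x^2 per series, so arbitrary-unit
rescaling of any one series leaves the objective unchanged), plus a
quadratic penalty that keeps the t = 0 state near a steady state of the
fitted rates.  Rate parameters are searched in log10 space (they span
orders of magnitude); spline knot values in linear space.

Each restart perturbs the base guess with multiplicative exponential-family
noise, runs a global particle-swarm search, then polishes with
Nelder-Mead.  A failed simulation returns a large sentinel objective so
the stochastic search can continue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .data import TimeSeriesDataset
from .models import ConfigurationError, ModelSpec, derived_observables, make_rhs, rhs
from .simulate import SimulationError, integrate_states, simulate

__all__ = [
    "FreeParameter",
    "FitProblem",
    "FitResult",
    "FitConfig",
    "default_free_parameters",
    "sse_objective",
    "perturb_initial_guess",
    "pso_optimize",
    "nelder_mead_refine",
    "multistart_fit",
]

#: objective value reported when a simulation fails inside the search
FAILURE_SENTINEL = 1e12


@dataclass(frozen=True)
class FreeParameter:
    """One free coordinate: a rate ``k1``..``k13`` or a deviation knot
    named ``<curve>@<time>`` (e.g. ``Retention@30``)."""

    name: str
    lower: float
    upper: float
    log: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ConfigurationError(f"bounds for {self.name} must be finite")
        if self.lower > self.upper:
            raise ConfigurationError(f"empty bounds for {self.name}")
        if self.log and self.lower <= 0:
            raise ConfigurationError(f"log-scale parameter {self.name} needs lower > 0")

    def to_internal(self, value: float) -> float:
        return math.log10(value) if self.log else value

    def from_internal(self, x: float) -> float:
        return 10.0 ** x if self.log else x

    @property
    def internal_bounds(self) -> tuple[float, float]:
        return self.to_internal(self.lower), self.to_internal(self.upper)


RATE_BOUNDS = (1e-3, 1e5)
KNOT_BOUNDS = {"multiplicative": (0.0, 50.0), "additive": (0.0, 100.0)}
#: canonical rates free by default; k4, k5 stay at their literature values
FREE_CANONICAL = ("k1", "k2", "k3", "k6", "k7", "k8")
VARIANT_RATES = {"H0": (), "M1": (), "M2": ("k9",), "M3": ("k10", "k11"),
                 "M4": ("k12", "k13"), "M5": ()}


def default_free_parameters(
    variant: str,
    knot_times: Sequence[float] = (2.0, 5.0, 10.0, 30.0, 60.0, 120.0),
    free_t0_knot: bool = False,
) -> list[FreeParameter]:
    """The default free set: canonical rates k1-k3/k6-k8, the variant's
    pseudo-reaction rates, and the deviation knots.  The t = 0 knot stays
    at its neutral value unless ``free_t0_knot`` so the pre-stimulation
    steady state is preserved."""
    from .models import deviation_info

    lo, hi = RATE_BOUNDS
    params = [FreeParameter(k, lo, hi, log=True) for k in FREE_CANONICAL]
    params += [FreeParameter(k, lo, hi, log=True) for k in VARIANT_RATES[variant]]
    dev, mode, _neutral = deviation_info(variant)
    if dev is not None:
        kb = KNOT_BOUNDS[mode]
        times = ((0.0,) if free_t0_knot else ()) + tuple(knot_times)
        params += [FreeParameter(f"{dev}@{t:g}", kb[0], kb[1]) for t in times]
    return params


@dataclass(frozen=True)
class FitProblem:
    """A calibration target: template spec, free coordinates, data."""

    template: ModelSpec
    free: tuple[FreeParameter, ...]
    data: TimeSeriesDataset
    condition: str = "serum"
    species: tuple[str, ...] | None = None    # default: all species in data
    ss_penalty: float = 1e3
    rtol: float = 1e-6
    atol: float = 1e-8

    def __post_init__(self) -> None:
        object.__setattr__(self, "free", tuple(self.free))
        names = [p.name for p in self.free]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate free parameter names")
        dev = self.template.deviation_name
        for p in self.free:
            if "@" in p.name:
                curve, t = p.name.split("@")
                if curve != dev:
                    raise ConfigurationError(
                        f"knot {p.name} does not belong to the declared deviation {dev!r}"
                    )
                if float(t) not in self.template.deviations[curve].knot_times:
                    raise ConfigurationError(f"no knot at t={t} in {curve!r}")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([p.internal_bounds for p in self.free])

    def named(self, theta: Sequence[float]) -> dict[str, float]:
        return {p.name: p.from_internal(x) for p, x in zip(self.free, theta)}

    def theta_of(self, values: Mapping[str, float]) -> np.ndarray:
        return np.array([p.to_internal(values[p.name]) for p in self.free])

    def build_spec(self, theta: Sequence[float]) -> ModelSpec:
        values = self.named(theta)
        rate_updates = {k: v for k, v in values.items() if not k.startswith("init:") and "@" not in k}
        spec = self.template
        if rate_updates:
            spec = replace(spec, rates=spec.rates.replace(**rate_updates))
        knots = [(k, v) for k, v in values.items() if "@" in k]
        if knots:
            curve = spec.deviations[spec.deviation_name]
            for name, v in knots:
                curve = curve.with_value(float(name.split("@")[1]), v)
            spec = spec.with_deviation(curve)
        return spec

    def base_guess(self) -> np.ndarray:
        """The template's own rates and deviation-knot values, clipped
        into bounds — the anchor that each restart perturbs.  Passing a
        previously fitted spec as the template therefore warm-starts the
        search from that fit."""
        values: dict[str, float] = {}
        rates = self.template.rates.as_dict()
        for p in self.free:
            if "@" in p.name:
                curve, t = p.name.split("@")
                v = float(self.template.deviations[curve](float(t)))
            else:
                v = rates[p.name]
            values[p.name] = min(max(v, p.lower if p.lower > 0 else p.lower), p.upper)
        # log-scale coordinates cannot sit at a zero lower bound
        for p in self.free:
            if p.log and values[p.name] <= 0:
                values[p.name] = math.sqrt(p.lower * p.upper)
        return self.theta_of(values)


def sse_objective(theta: Sequence[float], problem: FitProblem) -> float:
    """Weighted SSE at ``theta`` plus the steady-state penalty.

    Returns :data:`FAILURE_SENTINEL` when the simulation fails, so
    stochastic search simply routes around the bad region.
    """
    theta = np.clip(np.asarray(theta, dtype=float),
                    problem.bounds[:, 0], problem.bounds[:, 1])
    try:
        spec = problem.build_spec(theta)
    except (ConfigurationError, ValueError):
        return FAILURE_SENTINEL
    data = problem.data
    species = problem.species or tuple(
        s for s in data.species
        if not data.records[(data.records["species"] == s)
                            & (data.records["condition"] == problem.condition)].empty
    )
    times = np.sort(data.records[data.records["condition"] == problem.condition]
                    ["time_min"].unique())
    try:
        traj = simulate(spec, times, rtol=problem.rtol, atol=problem.atol)
    except SimulationError:
        return FAILURE_SENTINEL
    weights = data.weights()
    total = 0.0
    for s in species:
        med = data.series(s, problem.condition)
        sim = traj.at(med.index.to_numpy(), s)
        w = weights[(s, problem.condition)]
        total += w * float(np.sum((med.to_numpy() - sim) ** 2))
    if problem.ss_penalty > 0:
        f0 = rhs(spec, spec.y0(), 0.0)
        total += problem.ss_penalty * float(np.dot(f0, f0))
    return total


def compile_objective(problem: FitProblem) -> Callable[[np.ndarray], float]:
    """A fast closure computing the same value as :func:`sse_objective`
    with the data arrays and weights extracted once."""
    data = problem.data
    weights = data.weights()
    df = data.records[data.records["condition"] == problem.condition]
    species = problem.species or tuple(df["species"].unique())
    times = np.sort(df["time_min"].unique())
    series = []
    for s in species:
        med = data.series(s, problem.condition)
        idx = np.searchsorted(times, med.index.to_numpy())
        series.append((idx, med.to_numpy(), weights[(s, problem.condition)], s))
    lo, hi = None, None

    def objective(theta: np.ndarray) -> float:
        nonlocal lo, hi
        if lo is None:
            b = problem.bounds
            lo, hi = b[:, 0], b[:, 1]
        theta = np.clip(np.asarray(theta, dtype=float), lo, hi)
        try:
            spec = problem.build_spec(theta)
            y = integrate_states(spec, times, problem.rtol, problem.atol)
        except (ConfigurationError, ValueError, SimulationError):
            return FAILURE_SENTINEL
        obs = derived_observables(y, spec.variant)
        total = 0.0
        for idx, values, w, name in series:
            total += w * float(np.sum((values - obs[name][idx]) ** 2))
        if problem.ss_penalty > 0:
            f0 = make_rhs(spec)(spec.y0(), 0.0)
            total += problem.ss_penalty * float(np.dot(f0, f0))
        return total

    return objective


def perturb_initial_guess(
    params: np.ndarray, alpha: float, rng: np.random.Generator,
    bounds: np.ndarray | None = None,
) -> np.ndarray:
    """Multiplicative exponential-family perturbation of a (positive)
    parameter vector: each coordinate is multiplied by
    ``(1 - alpha) + alpha * E`` with ``E ~ Exp(mean 1)``.  The factor has
    unit mean for every ``alpha`` and degenerates to a no-op as
    ``alpha -> 0``."""
    if alpha < 0:
        raise ConfigurationError("alpha must be >= 0")
    params = np.asarray(params, dtype=float)
    factors = (1.0 - alpha) + alpha * rng.exponential(1.0, size=params.shape)
    out = params * factors
    if bounds is not None:
        out = np.clip(out, bounds[:, 0], bounds[:, 1])
    return out


@dataclass(frozen=True)
class FitConfig:
    """Optimizer budget.  The defaults are a reduced budget sized for
    desk-scale runs; ``full_scale()`` gives a study-size budget."""

    swarm_size: int = 20
    pso_iters: int = 30
    nm_maxfev: int = 300
    nm_tol: float = 1e-8
    alpha: float = 0.5
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618

    @classmethod
    def full_scale(cls) -> "FitConfig":
        return cls(swarm_size=40, pso_iters=200, nm_maxfev=2000)


def pso_optimize(
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    config: FitConfig = FitConfig(),
    seed: int | np.random.Generator = 0,
    x0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Global-best particle swarm within box bounds.

    Deterministic for a fixed seed.  Returns ``(best_x, best_f)``; the
    best value is never worse than the objective at ``x0``.
    """
    if config.swarm_size < 1 or config.pso_iters < 1:
        raise ConfigurationError("swarm size and iteration count must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    d = len(lo)
    n = config.swarm_size
    pos = lo + rng.uniform(size=(n, d)) * span
    if x0 is not None:
        pos[0] = np.clip(x0, lo, hi)
    vel = rng.uniform(-0.1, 0.1, size=(n, d)) * span
    pbest = pos.copy()
    pbest_f = np.array([objective(p) for p in pos])
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])
    for _ in range(config.pso_iters):
        r1 = rng.uniform(size=(n, d))
        r2 = rng.uniform(size=(n, d))
        vel = (config.inertia * vel
               + config.cognitive * r1 * (pbest - pos)
               + config.social * r2 * (gbest - pos))
        vmax = 0.5 * span
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(n):
            f = objective(pos[i])
            if f < pbest_f[i]:
                pbest_f[i] = f
                pbest[i] = pos[i]
                if f < gbest_f:
                    gbest_f = float(f)
                    gbest = pos[i].copy()
    return gbest, gbest_f


def nelder_mead_refine(
    start: np.ndarray,
    objective: Callable[[np.ndarray], float],
    bounds: np.ndarray,
    config: FitConfig = FitConfig(),
) -> tuple[np.ndarray, float]:
    """Local simplex polish; the returned objective never exceeds the
    starting one (coordinates are clipped to bounds inside the
    objective)."""
    f0 = objective(start)
    if not math.isfinite(f0):
        raise ConfigurationError("non-finite objective at the refinement start")
    res = minimize(
        objective, np.asarray(start, dtype=float), method="Nelder-Mead",
        options={"xatol": config.nm_tol, "fatol": config.nm_tol,
                 "maxfev": config.nm_maxfev, "adaptive": True},
    )
    x = np.clip(res.x, bounds[:, 0], bounds[:, 1])
    f = objective(x)
    if f <= f0:
        return x, float(f)
    return np.asarray(start, dtype=float), float(f0)


@dataclass(frozen=True)
class FitResult:
    """One calibrated parameter vector with provenance."""

    params: dict[str, float]
    theta: np.ndarray
    objective: float
    restart_index: int
    seed: int
    n_failures: int = 0
    trace: tuple[float, ...] = ()

    def spec(self, problem: FitProblem) -> ModelSpec:
        return problem.build_spec(problem.theta_of(self.params))


def multistart_fit(
    problem: FitProblem,
    n_starts: int = 10,
    seed: int = 0,
    config: FitConfig = FitConfig(),
) -> list[FitResult]:
    """perturb -> PSO -> Nelder-Mead, repeated; results sorted ascending
    by objective.  All restart seeds derive from ``seed``."""
    if n_starts < 1:
        raise ConfigurationError("n_starts must be >= 1")
    bounds = problem.bounds
    guess = problem.base_guess()
    fast = compile_objective(problem)

    failures = 0

    def objective(theta: np.ndarray) -> float:
        nonlocal failures
        f = fast(theta)
        if f >= FAILURE_SENTINEL:
            failures += 1
        return f

    results: list[FitResult] = []
    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_starts)):
        rng = np.random.default_rng(child)
        failures = 0
        if i == 0:
            start = guess
        else:
            # perturb in natural space: map to values, jiggle, clip, map back
            natural = np.array([p.from_internal(x) for p, x in zip(problem.free, guess)])
            natural_bounds = np.array([(p.lower, p.upper) for p in problem.free])
            jiggled = perturb_initial_guess(natural, config.alpha, rng, natural_bounds)
            start = np.array([p.to_internal(v) for p, v in zip(problem.free, jiggled)])
        x1, f1 = pso_optimize(objective, bounds, config, rng, x0=start)
        x2, f2 = nelder_mead_refine(x1, objective, bounds, config)
        results.append(FitResult(
            params=problem.named(x2), theta=x2, objective=float(f2),
            restart_index=i, seed=seed, n_failures=failures,
            trace=(float(objective(start)), float(f1), float(f2)),
        ))
    if all(r.objective >= FAILURE_SENTINEL for r in results):
        raise SimulationError("every restart failed to simulate")
    return sorted(results, key=lambda r: r.objective)
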