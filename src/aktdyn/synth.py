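"""Synthetic study-like datasets.

Generates the full experimental bundle the hypothesis-exclusion protocol
consumes, without any external data: a ground-truth retention (M3) model
whose noiseless observables reproduce the published curve-shape anchors —
PIP3 peaking at 2 min, total-lysate Aktp308 peaking at 30 min before
declining to a lower steady level, total membrane Akt peaking at 5 min and
staying high through 30 min, membrane phospho-Akt rising and staying high,
and membrane PDK1 mirroring PIP3 — plus replicate densitometry noise and
the blot-normalization chain (loading-control division, fold-change from
t = 0, median increments across replicates, rescale-to-max).

The retention variant is the default ground truth deliberately: the
protocol's expected verdict pattern is then known a priori.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import TimeSeriesDataset, write_timeseries
from .models import InitialState, ModelSpec, RateParameters, build_initial_state
from .simulate import Intervention, Trajectory, apply_intervention, simulate
from .splines import MEASUREMENT_GRID, SplineCurve

__all__ = [
    "NoiseModel",
    "FixtureBundle",
    "default_truth_rates",
    "default_truth_init",
    "generate_pip3_input",
    "default_truth_spec",
    "generate_ground_truth",
    "add_replicate_noise",
    "densitometry_normalize",
    "make_fixture_bundle",
]

#: replicate counts per assay: total-lysate Aktp308, membrane Aktp308m,
#: membrane TotMemAkt, LY29 TotMemAkt
REPLICATES = {"Aktp308": 4, "Aktp308m": 3, "TotMemAkt": 6, "ly29": 3, "PDK1m": 3}

#: rescaling targets for the normalized series (arbitrary units)
RESCALE_MAX = {"Aktp308": 10.0, "TotMemAkt": 10.0, "Aktp308m": 5.0, "PDK1m": 3.5}

# Ground-truth constants.  Canonical rates k2, k4, k5, k8 keep their
# published H0 values; k1, k3, k6, k7 and the retention rates were chosen
# once so the noiseless observables land on the published shape anchors
# (PIP3 peak 2 min, Aktp308 peak 30 min with decline, TotMemAkt peak 5 min
# staying high, PDK1m mirroring PIP3) while the intervention conditions
# behave as observed (flat membrane Akt under the PIP3 clamp; membrane Akt
# retained but PDK1 lost after constitutive activation + clamp).
_TRUTH_RATES = dict(k1=2.4, k3=0.6, k6=0.83, k7=1.65, k10=3.3, k11=0.095)
_TRUTH_PDK1M0 = 0.004
_PIP3_SHAPE = (3.0, 2.0, 1.2, 0.95, 0.9, 0.9)        # values at t = 2..120
_RETENTION_KNOTS = (0.0, 1.0, 3.1, 1.3, 1.8, 0.07, 0.015)


def default_truth_rates() -> RateParameters:
    return RateParameters(**_TRUTH_RATES)


def default_truth_init() -> InitialState:
    """Serum-starved initial state: essentially all PDK1 and Akt cytosolic."""
    return build_initial_state(
        free={"PDK1": 10.0 - _TRUTH_PDK1M0, "Aktc": 9.988,
              "PIP3:Aktm": 0.001, "Aktp308m": 0.001},
        variant="M3",
    )


def generate_pip3_input(
    baseline: float | None = None,
    peak: float = _PIP3_SHAPE[0],
    rates: RateParameters | None = None,
    init: InitialState | None = None,
) -> SplineCurve:
    """The serum-stimulation PIP3 input: a spike at 2 min declining to a
    moderate plateau.  The t = 0 baseline defaults to the value that
    balances the PDK1 shuttle at the ground-truth initial state."""
    if baseline is None:
        rates = rates or default_truth_rates()
        init = init or default_truth_init()
        baseline = rates.k2 * init["PIP3:PDK1m"] / (rates.k1 * init["PDK1"])
    scale = peak / _PIP3_SHAPE[0]
    tail = [max(v * scale, baseline) for v in _PIP3_SHAPE[1:]]
    return SplineCurve.on_grid([baseline, peak] + tail)


def default_retention_curve() -> SplineCurve:
    return SplineCurve.on_grid(_RETENTION_KNOTS)


def default_truth_spec() -> ModelSpec:
    """The retention-model ground truth behind the default bundle."""
    return ModelSpec(
        "M3",
        rates=default_truth_rates(),
        init=default_truth_init(),
        inputs={"PIP3": generate_pip3_input()},
        deviations={"Retention": default_retention_curve()},
    )


def generate_ground_truth(
    spec: ModelSpec | None = None,
    grid: Sequence[float] | None = None,
    activation_minutes: float = 240.0,
) -> dict[str, Trajectory]:
    """Noiseless trajectories for the three experiment conditions.

    ``serum``: the measured PIP3 spike drives the system.  ``ly29``: PIP3
    clamped at its unstimulated baseline for the whole simulation, the
    serum-induced deviation maintained.  ``shutdown``: the system is first
    driven to a constitutively activated plateau (high constant PIP3 with
    the deviation held at its maximum), then PIP3 is clamped low and the
    decay is simulated.
    """
    spec = spec or default_truth_spec()
    baseline = float(spec.inputs["PIP3"].knot_values[0])
    out = {"serum": simulate(spec, grid)}
    clamped = apply_intervention(spec, Intervention("clamp_input", "PIP3", baseline))
    out["ly29"] = simulate(clamped, grid)

    peak_pip3 = max(spec.inputs["PIP3"].knot_values)
    act = spec.with_input("PIP3", SplineCurve.constant(peak_pip3, (0, activation_minutes)))
    if spec.deviation_name is not None:
        hold = max(spec.deviations[spec.deviation_name].knot_values)
        act = act.with_deviation(SplineCurve.constant(hold, (0, activation_minutes)))
    tr_act = simulate(act, np.linspace(0.0, activation_minutes, int(activation_minutes) + 1))
    activated = InitialState(
        dict(zip(act.species, tr_act.states.iloc[-1])),
        spec.init.pdk1_total, spec.init.akt_total, spec.init.phosphatase,
    )
    shut = act.with_input("PIP3", SplineCurve.constant(baseline))
    shut = ModelSpec(shut.variant, rates=shut.rates, init=activated,
                     inputs=shut.inputs, deviations=shut.deviations)
    out["shutdown"] = simulate(shut, grid)
    return out


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative blot noise: an independent lognormal factor per
    measurement plus one lognormal batch factor per replicate series.
    ``sigma = 0`` reproduces the ground truth exactly."""

    sigma: float = 0.2
    batch_sigma: float = 0.15
    control_sigma: float = 0.05

    def __post_init__(self) -> None:
        if min(self.sigma, self.batch_sigma, self.control_sigma) < 0:
            raise ValueError("noise sigmas must be >= 0")


def _lognormal(rng: np.random.Generator, sigma: float, size=None):
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def add_replicate_noise(
    times: Sequence[float],
    values: Sequence[float],
    noise: NoiseModel,
    n_replicates: int,
    rng: np.random.Generator,
    species: str = "Aktp308",
    condition: str = "serum",
) -> pd.DataFrame:
    """Raw replicate densitometry: truth x batch factor x lognormal noise,
    with a matched noisy loading-control row per measurement."""
    rows = []
    values = np.asarray(values, dtype=float)
    for rep in range(1, n_replicates + 1):
        batch = _lognormal(rng, noise.batch_sigma)
        meas = values * batch * _lognormal(rng, noise.sigma, len(values))
        control = _lognormal(rng, noise.control_sigma, len(values))
        for t, v, c in zip(times, meas, control):
            rows.append({"species": species, "condition": condition,
                         "replicate": rep, "time_min": t,
                         "value": v, "control": c})
    return pd.DataFrame(rows)


def densitometry_normalize(
    replicates: pd.DataFrame,
    target_max: float,
    rescale_reference: str | None = None,
    cap_series: pd.Series | None = None,
) -> TimeSeriesDataset:
    """The blot-normalization chain applied to raw replicate tables.

    Per replicate: divide by the loading control, convert to fold-change
    from t = 0, difference into per-interval increments.  Across
    replicates: take the median increment per interval, accumulate back
    into a median series, and rescale so the maximum of the reference
    condition (default: the condition itself) equals ``target_max``.
    Negative cumulative excursions clip at zero; ``cap_series`` optionally
    caps the result at a matching total-lysate series.
    """
    req = {"species", "condition", "replicate", "time_min", "value", "control"}
    if not req.issubset(replicates.columns):
        raise ValueError(f"replicate table needs columns {sorted(req)}")
    if (replicates["control"] <= 0).any():
        raise ValueError("loading-control values must be positive")

    medians: dict[str, pd.Series] = {}
    for cond, group in replicates.groupby("condition"):
        increments = []
        for _, rep in group.groupby("replicate"):
            rep = rep.sort_values("time_min")
            corrected = rep["value"].to_numpy() / rep["control"].to_numpy()
            if corrected[0] <= 0:
                raise ValueError("zero value at t = 0: fold-change undefined")
            fold = corrected / corrected[0]
            increments.append(np.diff(fold))
        med_inc = np.median(np.vstack(increments), axis=0)
        series = np.concatenate([[1.0], 1.0 + np.cumsum(med_inc)])
        times = np.sort(group["time_min"].unique())
        medians[cond] = pd.Series(np.clip(series, 0.0, None), index=times)

    ref = rescale_reference or next(iter(medians))
    ref_max = medians[ref].max()
    if ref_max <= 0:
        raise ValueError("cannot rescale an all-zero median series")
    scale = target_max / ref_max

    species = replicates["species"].iloc[0]
    parts = []
    for cond, series in medians.items():
        values = series.to_numpy() * scale
        if cap_series is not None:
            cap = np.interp(series.index.to_numpy(), cap_series.index.to_numpy(),
                            cap_series.to_numpy())
            values = np.minimum(values, cap)
        parts.append(pd.DataFrame({
            "species": species, "condition": cond, "replicate": "median",
            "time_min": series.index.to_numpy(), "value": values,
        }))
    return TimeSeriesDataset(pd.concat(parts, ignore_index=True))


@dataclass(frozen=True)
class FixtureBundle:
    """Everything the protocol needs, plus the generating truth."""

    pip3: SplineCurve
    datasets: Mapping[str, TimeSeriesDataset]   # keys: aktp308, membrane, ly29, shutdown
    truth: ModelSpec
    truth_trajectories: Mapping[str, Trajectory]
    manifest: dict = field(default_factory=dict)

    def dataset(self, key: str) -> TimeSeriesDataset:
        return self.datasets[key]

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for key, ds in self.datasets.items():
            write_timeseries(ds, directory / f"{key}.csv")
        pd.DataFrame({
            "time_min": self.pip3.knot_times, "value": self.pip3.knot_values,
        }).to_csv(directory / "pip3.csv", index=False)
        for cond, traj in self.truth_trajectories.items():
            traj.to_tidy(cond).to_csv(directory / f"truth_{cond}.csv", index=False)
        (directory / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def make_fixture_bundle(
    seed: int = 0,
    noise: NoiseModel | None = None,
    truth: ModelSpec | None = None,
    out_dir: str | Path | None = None,
) -> FixtureBundle:
    """Build the seeded default bundle (write it to ``out_dir`` if given)."""
    noise = NoiseModel() if noise is None else noise
    truth = truth or default_truth_spec()
    rng = np.random.default_rng(seed)
    trajs = generate_ground_truth(truth)
    grid = list(MEASUREMENT_GRID)

    def series(cond: str, name: str) -> np.ndarray:
        return trajs[cond].at(grid, name)

    raw = {
        ("Aktp308", "serum"): add_replicate_noise(
            grid, series("serum", "Aktp308"), noise, REPLICATES["Aktp308"], rng,
            "Aktp308", "serum"),
        ("PDK1m", "serum"): add_replicate_noise(
            grid, series("serum", "PDK1m"), noise, REPLICATES["PDK1m"], rng,
            "PDK1m", "serum"),
        ("TotMemAkt", "serum"): add_replicate_noise(
            grid, series("serum", "TotMemAkt"), noise, REPLICATES["TotMemAkt"], rng,
            "TotMemAkt", "serum"),
        ("Aktp308m", "serum"): add_replicate_noise(
            grid, series("serum", "Aktp308m"), noise, REPLICATES["Aktp308m"], rng,
            "Aktp308m", "serum"),
        ("TotMemAkt", "ly29"): add_replicate_noise(
            grid, series("ly29", "TotMemAkt"), noise, REPLICATES["ly29"], rng,
            "TotMemAkt", "ly29"),
    }

    aktp308 = densitometry_normalize(raw[("Aktp308", "serum")],
                                     RESCALE_MAX["Aktp308"])
    lysate_median = aktp308.series("Aktp308", "serum")
    membrane = TimeSeriesDataset.concat([
        densitometry_normalize(raw[("PDK1m", "serum")], RESCALE_MAX["PDK1m"]),
        densitometry_normalize(raw[("TotMemAkt", "serum")], RESCALE_MAX["TotMemAkt"]),
        densitometry_normalize(raw[("Aktp308m", "serum")], RESCALE_MAX["Aktp308m"],
                               cap_series=lysate_median),
    ])
    ly29 = densitometry_normalize(
        pd.concat([raw[("TotMemAkt", "serum")], raw[("TotMemAkt", "ly29")]],
                  ignore_index=True),
        RESCALE_MAX["TotMemAkt"], rescale_reference="serum",
    ).subset(condition="ly29")

    # shutdown endpoints: membrane Akt and PDK1 at the clamp and 120 min later
    shut = trajs["shutdown"]
    rows = []
    for name in ("TotMemAkt", "PDK1m"):
        for t in (0.0, 120.0):
            value = float(shut.at([t], name)[0])
            value *= _lognormal(rng, noise.sigma)
            rows.append({"species": name, "condition": "shutdown",
                         "replicate": 1, "time_min": t, "value": value})
    shutdown = TimeSeriesDataset(pd.DataFrame(rows))

    manifest = {
        "seed": seed,
        "variant": truth.variant,
        "noise": {"sigma": noise.sigma, "batch_sigma": noise.batch_sigma,
                  "control_sigma": noise.control_sigma},
        "rates": truth.rates.as_dict(),
        "replicates": dict(REPLICATES),
        "rescale_max": dict(RESCALE_MAX),
        "grid": grid,
    }
    bundle = FixtureBundle(
        pip3=truth.inputs["PIP3"],
        datasets={"aktp308": aktp308, "membrane": membrane,
                  "ly29": ly29, "shutdown": shutdown},
        truth=truth,
        truth_trajectories=trajs,
        manifest=manifest,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle
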