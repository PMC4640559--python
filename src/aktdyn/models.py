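"""The six pathway model variants.

The canonical cascade (H0) runs PIP3 -> PDK1 recruitment and
PIP3 -> Akt recruitment, membrane phosphorylation of Akt at Thr308 by
PIP3:PDK1m, dissociation of phospho-Akt back to the cytosol, and cytosolic
dephosphorylation by a lumped Phosphatase pool:

    PDK1      <-> PIP3:PDK1m          (k1*PIP3*PDK1 / k2*[PIP3:PDK1m])
    Aktc       -> PIP3:Aktm           (k3*PIP3*Aktc)
    PIP3:Aktm  -> Aktp308m            (k4*[PIP3:PDK1m]*[PIP3:Aktm]/(k5+[PIP3:Aktm]))
    Aktp308m   -> Aktp308c            (k6*[Aktp308m])
    Aktp308c   -> Aktc                (k7*[Phosphatase]*[Aktp308c]/(k8+[Aktp308c]))

PIP3 is a measured input curve, never a governed species: it appears as a
pure multiplier in the recruitment terms and is never depleted.

Each alternative variant (M1-M5) adds exactly one non-canonical deviation,
a spline-valued pseudo-species coupled through a pseudo-reaction:

    M1  PIP3-dependent recruitment:  k3*PIP3*[Recruitment]*Aktc (multiplicative)
    M2  PIP3-independent recruitment: extra flux k9*[Recruitment]*Aktc
    M3  membrane retention: Aktp308m splits into free (mf) and trapped (mt)
        pools, with trapping k10*[Retention]*mf and release k11*mt
    M4  phosphatase sequestration: Phosphatase <-> InaccPhosphatase with
        forward flux k12*[Sequestration]*[Phosphatase] and return k13
    M5  phosphorylation modulation: k4*[PIP3:PDK1m]*[Phosphorylation]*
        [PIP3:Aktm]/(k5+[PIP3:Aktm]) (multiplicative)

The M4 coupling deserves a note: the sequestration flux is driven
multiplicatively by the deviation curve so that M4 follows the same
pseudo-species scheme as the other variants (deviation == 0 recovers H0
exactly).  The Phosphatase pool is dynamic only in M4; every other variant
holds it constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .splines import SplineCurve

__all__ = [
    "VARIANTS",
    "RateParameters",
    "InitialState",
    "ModelSpec",
    "ConfigurationError",
    "InvalidStateError",
    "species_names",
    "deviation_info",
    "build_initial_state",
    "make_rhs",
    "rhs",
    "derived_observables",
    "steady_state_input_baseline",
    "steady_state_init",
]

VARIANTS = ("H0", "M1", "M2", "M3", "M4", "M5")

#: deviation curve name, coupling mode and neutral value per variant
_DEVIATIONS: dict[str, tuple[str | None, str, float]] = {
    "H0": (None, "none", 0.0),
    "M1": ("Recruitment", "multiplicative", 1.0),
    "M2": ("Recruitment", "additive", 0.0),
    "M3": ("Retention", "additive", 0.0),
    "M4": ("Sequestration", "additive", 0.0),
    "M5": ("Phosphorylation", "multiplicative", 1.0),
}

_BASE_SPECIES = ("PDK1", "PIP3:PDK1m", "Aktc", "PIP3:Aktm", "Aktp308m", "Aktp308c")
_M3_SPECIES = ("PDK1", "PIP3:PDK1m", "Aktc", "PIP3:Aktm", "Aktp308mf", "Aktp308mt", "Aktp308c")
_M4_SPECIES = _BASE_SPECIES + ("Phosphatase", "InaccPhosphatase")


class ConfigurationError(ValueError):
    """Ill-formed model configuration."""


class InvalidStateError(ValueError):
    """A state closure produced a negative concentration."""


def species_names(variant: str) -> tuple[str, ...]:
    """Governed-species ordering for ``variant`` (fixed across the package)."""
    if variant == "M3":
        return _M3_SPECIES
    if variant == "M4":
        return _M4_SPECIES
    if variant in VARIANTS:
        return _BASE_SPECIES
    raise ConfigurationError(f"unknown variant {variant!r}")


def deviation_info(variant: str) -> tuple[str | None, str, float]:
    """(curve name, coupling mode, neutral value) for ``variant``."""
    try:
        return _DEVIATIONS[variant]
    except KeyError:
        raise ConfigurationError(f"unknown variant {variant!r}") from None


@dataclass(frozen=True)
class RateParameters:
    """Rate constants.  k1-k8 are the canonical rates (defaults are the
    published H0 estimates); k9-k13 belong to the variant-specific
    pseudo-reactions and default to zero (neutral)."""

    k1: float = 1.79
    k2: float = 9.9
    k3: float = 5.27
    k4: float = 2450.0
    k5: float = 68000.0
    k6: float = 0.49
    k7: float = 5.0
    k8: float = 1.65
    k9: float = 0.0
    k10: float = 0.0
    k11: float = 0.0
    k12: float = 0.0
    k13: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if value < 0:
                raise ConfigurationError(f"rate {name} must be >= 0, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {f"k{i}": getattr(self, f"k{i}") for i in range(1, 14)}

    def replace(self, **updates: float) -> "RateParameters":
        return replace(self, **updates)


@dataclass(frozen=True)
class InitialState:
    """Initial concentrations with the conservation closures applied.

    ``PIP3:PDK1m`` and ``Aktp308c`` are always the derived complements of
    the respective totals; construct instances through
    :func:`build_initial_state` so the closures hold.
    """

    concentrations: Mapping[str, float]
    pdk1_total: float = 10.0
    akt_total: float = 10.0
    phosphatase: float = 0.24

    def __getitem__(self, name: str) -> float:
        if name == "Phosphatase":
            return self.concentrations.get("Phosphatase", self.phosphatase)
        return self.concentrations[name]

    def vector(self, variant: str) -> np.ndarray:
        return np.array([self[name] for name in species_names(variant)], dtype=float)


def build_initial_state(
    totals: Mapping[str, float] | None = None,
    free: Mapping[str, float] | None = None,
    variant: str = "H0",
) -> InitialState:
    """Fill in the derived initial concentrations.

    ``totals`` may override ``PDK1_total`` / ``Akt_total`` (default 10 each);
    ``free`` may override the directly specified pools (``PDK1``, ``Aktc``,
    ``PIP3:Aktm``, ``Aktp308m``, ``Phosphatase``).  ``PIP3:PDK1m`` and
    ``Aktp308c`` are derived so the totals close exactly.  For M3 the given
    ``Aktp308m`` seeds the free pool (trapped pool starts empty); for M4 the
    inaccessible phosphatase pool starts empty.
    """
    totals = dict(totals or {})
    free = dict(free or {})
    pdk1_total = float(totals.get("PDK1_total", 10.0))
    akt_total = float(totals.get("Akt_total", 10.0))
    pdk1 = float(free.get("PDK1", 9.75))
    aktc = float(free.get("Aktc", 9.988))
    aktm = float(free.get("PIP3:Aktm", 0.001))
    aktp308m = float(free.get("Aktp308m", 0.001))
    phosphatase = float(free.get("Phosphatase", 0.24))

    for name, value in [("PDK1_total", pdk1_total), ("Akt_total", akt_total),
                        ("PDK1", pdk1), ("Aktc", aktc), ("PIP3:Aktm", aktm),
                        ("Aktp308m", aktp308m), ("Phosphatase", phosphatase)]:
        if value < 0:
            raise InvalidStateError(f"{name} must be >= 0, got {value}")

    pip3_pdk1m = pdk1_total - pdk1
    aktp308c = akt_total - aktc - aktm - aktp308m
    if pip3_pdk1m < 0:
        raise InvalidStateError(f"PDK1 ({pdk1}) exceeds PDK1_total ({pdk1_total})")
    if aktp308c < 0:
        raise InvalidStateError(
            f"Akt pools ({aktc} + {aktm} + {aktp308m}) exceed Akt_total ({akt_total})"
        )

    conc: dict[str, float] = {
        "PDK1": pdk1,
        "PIP3:PDK1m": pip3_pdk1m,
        "Aktc": aktc,
        "PIP3:Aktm": aktm,
        "Aktp308c": aktp308c,
        "Phosphatase": phosphatase,
    }
    if variant == "M3":
        conc["Aktp308mf"] = aktp308m
        conc["Aktp308mt"] = 0.0
    else:
        conc["Aktp308m"] = aktp308m
    if variant == "M4":
        conc["InaccPhosphatase"] = 0.0
    return InitialState(conc, pdk1_total, akt_total, phosphatase)


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified pathway variant ready for simulation."""

    variant: str
    rates: RateParameters = field(default_factory=RateParameters)
    init: InitialState | None = None
    inputs: Mapping[str, SplineCurve] = field(default_factory=dict)
    deviations: Mapping[str, SplineCurve] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if "PIP3" not in self.inputs:
            raise ConfigurationError("a PIP3 input curve is mandatory")
        name, _, _ = deviation_info(self.variant)
        if name is None:
            if self.deviations:
                raise ConfigurationError("H0 takes no deviation curves")
        elif name not in self.deviations:
            raise ConfigurationError(
                f"variant {self.variant} requires a {name!r} deviation curve"
            )
        if self.init is None:
            object.__setattr__(self, "init", build_initial_state(variant=self.variant))

    @property
    def species(self) -> tuple[str, ...]:
        return species_names(self.variant)

    @property
    def deviation_name(self) -> str | None:
        return deviation_info(self.variant)[0]

    def with_input(self, name: str, curve: SplineCurve) -> "ModelSpec":
        inputs = dict(self.inputs)
        inputs[name] = curve
        return replace(self, inputs=inputs)

    def with_deviation(self, curve: SplineCurve) -> "ModelSpec":
        name = self.deviation_name
        if name is None:
            raise ConfigurationError("H0 takes no deviation curves")
        return replace(self, deviations={name: curve})

    def y0(self) -> np.ndarray:
        return self.init.vector(self.variant)


def make_rhs(spec: ModelSpec) -> Callable[[np.ndarray, float], np.ndarray]:
    """Compile the variant's right-hand side as ``f(y, t) -> dy/dt``.

    Inputs and deviations are evaluated by spline interpolation at ``t``
    (they are never integrated).  The returned closure works on plain
    floats for speed inside the ODE solver.
    """
    k = spec.rates
    k1, k2, k3, k4, k5, k6, k7, k8 = k.k1, k.k2, k.k3, k.k4, k.k5, k.k6, k.k7, k.k8
    if k5 <= 0 or k8 < 0:
        raise ConfigurationError("Michaelis constants k5 and k8 must be positive")
    pip3_t = spec.inputs["PIP3"].knot_times
    pip3_v = spec.inputs["PIP3"].knot_values
    variant = spec.variant
    dev_name = spec.deviation_name
    if dev_name is not None:
        dev_t = spec.deviations[dev_name].knot_times
        dev_v = spec.deviations[dev_name].knot_values
    phosphatase = spec.init["Phosphatase"]

    def interp(t, xs, ys):
        # scalar linear interpolation, clamped at the ends
        if t <= xs[0]:
            return ys[0]
        if t >= xs[-1]:
            return ys[-1]
        lo, hi = 0, len(xs) - 1
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if xs[mid] <= t:
                lo = mid
            else:
                hi = mid
        x0, x1 = xs[lo], xs[hi]
        y0, y1 = ys[lo], ys[hi]
        return y0 + (y1 - y0) * (t - x0) / (x1 - x0)

    def f(y, t):
        pip3 = interp(t, pip3_t, pip3_v)
        dev = interp(t, dev_t, dev_v) if dev_name is not None else 0.0

        if variant == "M3":
            pdk1, pdk1m, aktc, aktm, mf, mt, ac = y
            v_on = k1 * pip3 * pdk1
            v_off = k2 * pdk1m
            v_rec = k3 * pip3 * aktc
            v_phos = k4 * pdk1m * aktm / (k5 + aktm)
            v_dis = k6 * mf
            v_deph = k7 * phosphatase * ac / (k8 + ac)
            v_trap = k.k10 * dev * mf
            v_rel = k.k11 * mt
            return np.array([
                -v_on + v_off,
                v_on - v_off,
                -v_rec + v_deph,
                v_rec - v_phos,
                v_phos - v_dis - v_trap + v_rel,
                v_trap - v_rel,
                v_dis - v_deph,
            ])

        if variant == "M4":
            pdk1, pdk1m, aktc, aktm, m, ac, ph, inacc = y
        else:
            pdk1, pdk1m, aktc, aktm, m, ac = y
            ph = phosphatase

        v_on = k1 * pip3 * pdk1
        v_off = k2 * pdk1m
        v_rec = k3 * pip3 * aktc
        if variant == "M1":
            v_rec *= dev
        v_phos = k4 * pdk1m * aktm / (k5 + aktm)
        if variant == "M5":
            v_phos *= dev
        v_dis = k6 * m
        v_deph = k7 * ph * ac / (k8 + ac)
        v9 = k.k9 * dev * aktc if variant == "M2" else 0.0

        d = [
            -v_on + v_off,
            v_on - v_off,
            -v_rec + v_deph - v9,
            v_rec - v_phos + v9,
            v_phos - v_dis,
            v_dis - v_deph,
        ]
        if variant == "M4":
            v_seq = k.k12 * dev * ph
            v_ret = k.k13 * inacc
            d.extend([-v_seq + v_ret, v_seq - v_ret])
        return np.array(d)

    return f


def rhs(spec: ModelSpec, state: np.ndarray, t: float) -> np.ndarray:
    """Derivative vector of ``spec`` at ``state`` and time ``t`` (minutes)."""
    return make_rhs(spec)(np.asarray(state, dtype=float), float(t))


def derived_observables(state: np.ndarray, variant: str) -> dict[str, float]:
    """Observables derived from a state vector.

    Aktp308 = Aktp308m + Aktp308c (total phospho-Akt); TotMemAkt =
    Aktp308m + PIP3:Aktm (all membrane-bound Akt); PDK1m = PIP3:PDK1m.
    For the retention model Aktp308m itself is the free + trapped sum.
    """
    names = species_names(variant)
    idx = {n: i for i, n in enumerate(names)}
    state = np.asarray(state, dtype=float)
    if variant == "M3":
        aktp308m = state[..., idx["Aktp308mf"]] + state[..., idx["Aktp308mt"]]
    else:
        aktp308m = state[..., idx["Aktp308m"]]
    aktp308c = state[..., idx["Aktp308c"]]
    return {
        "Aktp308": aktp308m + aktp308c,
        "TotMemAkt": aktp308m + state[..., idx["PIP3:Aktm"]],
        "PDK1m": state[..., idx["PIP3:PDK1m"]],
        "Aktp308m": aktp308m,
        "Aktp308c": aktp308c,
    }


def steady_state_input_baseline(
    rates: RateParameters, init: InitialState
) -> tuple[float, float]:
    """PIP3 baseline that balances the PDK1 shuttle at ``init``.

    Returns ``(PIP3_0, residual_norm)`` where ``PIP3_0 =
    k2*[PIP3:PDK1m]/(k1*[PDK1])`` and the residual is the norm of the full
    H0 derivative vector at ``init`` with that baseline — exactly zero only
    if all six equations balance (they need not).
    """
    pdk1 = init["PDK1"]
    if pdk1 <= 0:
        raise InvalidStateError("PDK1 must be > 0 to derive a PIP3 baseline")
    pip3_0 = rates.k2 * init["PIP3:PDK1m"] / (rates.k1 * pdk1)
    spec = ModelSpec(
        "H0", rates=rates, init=init,
        inputs={"PIP3": SplineCurve.constant(pip3_0)},
    )
    residual = float(np.linalg.norm(rhs(spec, spec.y0(), 0.0)))
    return pip3_0, residual


def steady_state_init(
    rates: RateParameters,
    pip3_baseline: float,
    pdk1_total: float = 10.0,
    akt_total: float = 10.0,
    phosphatase: float = 0.24,
) -> InitialState:
    """Solve for the H0 state that is exactly steady at a given PIP3 level.

    The PDK1 shuttle balances in closed form; the Akt cycle's common flux F
    satisfies a scalar mass-balance equation solved by bisection.  Useful
    for constructing genuinely drift-free baselines and the pre-activated
    states of the shutdown experiment.
    """
    k = rates
    if pip3_baseline < 0:
        raise InvalidStateError("PIP3 baseline must be >= 0")
    pdk1m = pdk1_total * k.k1 * pip3_baseline / (k.k1 * pip3_baseline + k.k2)
    pdk1 = pdk1_total - pdk1m
    if pip3_baseline == 0 or pdk1m == 0:
        free = {"PDK1": pdk1, "Aktc": akt_total, "PIP3:Aktm": 0.0,
                "Aktp308m": 0.0, "Phosphatase": phosphatase}
        return build_initial_state(
            {"PDK1_total": pdk1_total, "Akt_total": akt_total}, free
        )

    def akt_total_at(flux: float) -> float:
        # invert each steady-state relation for the pool sizes at this flux
        aktc = flux / (k.k3 * pip3_baseline)
        denom = k.k4 * pdk1m - flux
        aktm = math.inf if denom <= 0 else flux * k.k5 / denom
        m = flux / k.k6
        denom_c = k.k7 * phosphatase - flux
        ac = math.inf if denom_c <= 0 else flux * k.k8 / denom_c
        return aktc + aktm + m + ac

    lo, hi = 0.0, min(k.k4 * pdk1m, k.k7 * phosphatase) * (1 - 1e-12)
    if akt_total_at(hi) < akt_total:
        raise InvalidStateError("no steady state holds the requested Akt total")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if akt_total_at(mid) < akt_total:
            lo = mid
        else:
            hi = mid
    flux = 0.5 * (lo + hi)
    aktc = flux / (k.k3 * pip3_baseline)
    aktm = flux * k.k5 / (k.k4 * pdk1m - flux)
    m = flux / k.k6
    free = {"PDK1": pdk1, "Aktc": aktc, "PIP3:Aktm": aktm,
            "Aktp308m": m, "Phosphatase": phosphatase}
    return build_initial_state(
        {"PDK1_total": pdk1_total, "Akt_total": akt_total}, free
    )
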