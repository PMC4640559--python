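"""Pathway-variant definitions: state closures, kinetics, steady states.

The kinetics oracle here re-codes every variant's printed rate equations
independently of the package's rhs factory (plain dictionaries, no shared
code) and compares derivative vectors on random states.
"""

import numpy as np
import pytest

from aktdyn.models import (
    ConfigurationError,
    InvalidStateError,
    ModelSpec,
    RateParameters,
    build_initial_state,
    derived_observables,
    rhs,
    species_names,
    steady_state_init,
    steady_state_input_baseline,
)
from aktdyn.simulate import simulate
from aktdyn.splines import SplineCurve

from conftest import variant_spec

VARIANTS = ("H0", "M1", "M2", "M3", "M4", "M5")


# --- independent oracle ---------------------------------------------------

def oracle_rhs(variant, k, y, pip3, dev, phosphatase):
    """Hand-coded printed equations, one dict per variant."""
    if variant == "M3":
        pdk1, pdk1m, aktc, aktm, mf, mt, ac = y
    elif variant == "M4":
        pdk1, pdk1m, aktc, aktm, m, ac, ph, inacc = y
    else:
        pdk1, pdk1m, aktc, aktm, m, ac = y
        ph = phosphatase

    d = {}
    d["PDK1"] = -k["k1"] * pip3 * pdk1 + k["k2"] * pdk1m
    d["PIP3:PDK1m"] = k["k1"] * pip3 * pdk1 - k["k2"] * pdk1m
    phos = k["k4"] * pdk1m * aktm / (k["k5"] + aktm)
    if variant == "M5":
        phos = k["k4"] * pdk1m * dev * aktm / (k["k5"] + aktm)
    if variant == "M3":
        deph = k["k7"] * phosphatase * ac / (k["k8"] + ac)
        d["Aktc"] = -k["k3"] * pip3 * aktc + deph
        d["PIP3:Aktm"] = k["k3"] * pip3 * aktc - phos
        d["Aktp308mf"] = phos - k["k6"] * mf - k["k10"] * dev * mf + k["k11"] * mt
        d["Aktp308mt"] = k["k10"] * dev * mf - k["k11"] * mt
        d["Aktp308c"] = k["k6"] * mf - deph
        return np.array([d[n] for n in species_names("M3")])
    deph = k["k7"] * ph * ac / (k["k8"] + ac)
    rec = k["k3"] * pip3 * aktc
    if variant == "M1":
        rec = k["k3"] * pip3 * dev * aktc
    extra = k["k9"] * dev * aktc if variant == "M2" else 0.0
    d["Aktc"] = -rec + deph - extra
    d["PIP3:Aktm"] = rec - phos + extra
    d["Aktp308m"] = phos - k["k6"] * m
    d["Aktp308c"] = k["k6"] * m - deph
    if variant == "M4":
        d["Phosphatase"] = -k["k12"] * dev * ph + k["k13"] * inacc
        d["InaccPhosphatase"] = k["k12"] * dev * ph - k["k13"] * inacc
    return np.array([d[n] for n in species_names(variant)])


@pytest.mark.parametrize("variant", VARIANTS)
def test_rhs_matches_independent_equations(variant, truth_spec):
    rng = np.random.default_rng(42)
    spec = variant_spec(variant, truth_spec)
    k = spec.rates.as_dict()
    dev_name = spec.deviation_name
    for _ in range(100):
        y = rng.uniform(0.0, 10.0, len(spec.species))
        t = rng.uniform(0.0, 120.0)
        pip3 = float(spec.inputs["PIP3"](t))
        dev = float(spec.deviations[dev_name](t)) if dev_name else 0.0
        got = rhs(spec, y, t)
        want = oracle_rhs(variant, k, y, pip3, dev, spec.init["Phosphatase"])
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-14)


@pytest.mark.parametrize("variant", VARIANTS)
def test_rhs_conserves_pools(variant, truth_spec):
    """The printed equations are closed in the PDK1 and Akt pools (and the
    phosphatase pool for the sequestration variant)."""
    rng = np.random.default_rng(3)
    spec = variant_spec(variant, truth_spec)
    names = list(spec.species)
    akt = [i for i, n in enumerate(names)
           if n in ("Aktc", "PIP3:Aktm", "Aktp308m", "Aktp308mf",
                    "Aktp308mt", "Aktp308c")]
    pdk = [i for i, n in enumerate(names) if n in ("PDK1", "PIP3:PDK1m")]
    for _ in range(20):
        y = rng.uniform(0.0, 10.0, len(names))
        d = rhs(spec, y, rng.uniform(0, 120))
        assert abs(d[akt].sum()) < 1e-12
        assert abs(d[pdk].sum()) < 1e-12
        if variant == "M4":
            ph = [i for i, n in enumerate(names)
                  if n in ("Phosphatase", "InaccPhosphatase")]
            assert abs(d[ph].sum()) < 1e-12


@pytest.mark.parametrize("variant", ("M1", "M2", "M3", "M4", "M5"))
def test_neutral_deviation_reproduces_h0(variant, truth_spec):
    """Multiplicative deviations at 1 and additive deviations at 0 leave
    the canonical derivative field untouched."""
    from aktdyn.models import deviation_info

    rng = np.random.default_rng(11)
    _, mode, neutral = deviation_info(variant)
    spec = variant_spec(variant, truth_spec,
                        deviation_values=[neutral] * 7)
    h0 = variant_spec("H0", truth_spec)
    h0 = ModelSpec("H0", rates=spec.rates, init=h0.init, inputs=h0.inputs)
    names = list(spec.species)
    for _ in range(20):
        y_h0 = rng.uniform(0, 10, 6)
        y = np.zeros(len(names))
        mapping = {"Aktp308mf": "Aktp308m"}
        h0_names = list(h0.species)
        for i, n in enumerate(names):
            src = mapping.get(n, n)
            if src in h0_names:
                y[i] = y_h0[h0_names.index(src)]
            elif n == "Phosphatase":
                y[i] = spec.init["Phosphatase"]
            else:
                y[i] = 0.0  # trapped / inaccessible pools empty
        t = rng.uniform(0, 120)
        d = rhs(spec, y, t)
        d_h0 = rhs(h0, y_h0, t)
        collapsed = {}
        for i, n in enumerate(names):
            collapsed[mapping.get(n, n)] = collapsed.get(mapping.get(n, n), 0.0) + d[i]
        for j, n in enumerate(h0_names):
            assert collapsed[n] == pytest.approx(d_h0[j], abs=1e-12)


# --- initial-state closure ------------------------------------------------

def test_initial_state_closure_defaults():
    init = build_initial_state()
    assert init["PIP3:PDK1m"] == pytest.approx(0.25)
    assert init["Aktp308c"] == pytest.approx(0.01)
    total = init["Aktc"] + init["PIP3:Aktm"] + init["Aktp308m"] + init["Aktp308c"]
    assert total == pytest.approx(10.0)


def test_initial_state_closure_edge_cases():
    init = build_initial_state(free={"PDK1": 10.0})
    assert init["PIP3:PDK1m"] == 0.0
    with pytest.raises(InvalidStateError):
        build_initial_state(free={"Aktc": 10.5})
    m3 = build_initial_state(variant="M3")
    assert m3["Aktp308mf"] == pytest.approx(0.001)
    assert m3["Aktp308mt"] == 0.0
    m4 = build_initial_state(variant="M4")
    assert m4["InaccPhosphatase"] == 0.0


# --- derived observables --------------------------------------------------

def test_derived_observables_definitions():
    y = dict(zip(species_names("H0"), [9.75, 0.25, 2.0, 0.5, 3.0, 4.0]))
    obs = derived_observables(np.array(list(y.values())), "H0")
    assert obs["Aktp308"] == pytest.approx(7.0)
    assert obs["TotMemAkt"] == pytest.approx(3.5)
    assert obs["PDK1m"] == pytest.approx(0.25)


def test_derived_observables_retention_pools_sum():
    y = dict(zip(species_names("M3"), [9.75, 0.25, 2.0, 0.5, 1.0, 2.0, 4.0]))
    obs = derived_observables(np.array(list(y.values())), "M3")
    assert obs["Aktp308m"] == pytest.approx(3.0)
    assert obs["TotMemAkt"] == pytest.approx(3.5)
    assert obs["Aktp308"] == pytest.approx(7.0)


def test_default_initial_membrane_akt():
    init = build_initial_state()
    obs = derived_observables(init.vector("H0"), "H0")
    assert obs["TotMemAkt"] == pytest.approx(0.002)


# --- steady states --------------------------------------------------------

def test_input_baseline_from_pdk1_balance():
    rates = RateParameters()
    init = build_initial_state()
    pip3_0, residual = steady_state_input_baseline(rates, init)
    assert pip3_0 == pytest.approx(9.9 * 0.25 / (1.79 * 9.75), rel=1e-12)
    assert pip3_0 == pytest.approx(0.14182, rel=1e-4)
    # the PDK1 pair balances but the Akt cycle does not: honest residual
    assert residual > 1.0


def test_input_baseline_zero_when_no_membrane_pdk1():
    init = build_initial_state(free={"PDK1": 10.0})
    pip3_0, _ = steady_state_input_baseline(RateParameters(), init)
    assert pip3_0 == 0.0


def test_solved_steady_state_is_stationary():
    rates = RateParameters()
    init = steady_state_init(rates, 0.14182)
    spec = ModelSpec("H0", rates=rates, init=init,
                     inputs={"PIP3": SplineCurve.constant(0.14182)})
    f0 = rhs(spec, spec.y0(), 0.0)
    assert np.linalg.norm(f0) < 1e-8
    traj = simulate(spec)
    drift = np.abs(traj.states.to_numpy() - traj.states.to_numpy()[0])
    rel = drift / (np.abs(traj.states.to_numpy()[0]) + 1e-12)
    assert rel.max() < 1e-6


def test_spec_requires_pip3_and_matching_deviation():
    with pytest.raises(ConfigurationError):
        ModelSpec("H0", inputs={})
    with pytest.raises(ConfigurationError):
        ModelSpec("M3", inputs={"PIP3": SplineCurve.constant(1.0)})
    with pytest.raises(ConfigurationError):
        ModelSpec("H0", inputs={"PIP3": SplineCurve.constant(1.0)},
                  deviations={"Retention": SplineCurve.constant(1.0)})
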