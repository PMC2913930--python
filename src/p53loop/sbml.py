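"""SBML Level 3 Version 2 exchange for the loop model.

The document encodes the model reaction-wise — the same ten channels the
stochastic layer uses — with MathML kinetic laws that reproduce the
deterministic right-hand side, so the ODE, SSA and SBML views share one
source of truth.  Import parses the MathML subset the writer emits
(times, plus, minus, divide, power over symbols and numbers) into sympy
expressions; :func:`diff_rhs` reports term-level discrepancies between a
foreign document and the package's own equations instead of silently
overwriting either.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy as sp
from lxml import etree

from .params import ModelParameters

__all__ = [
    "SBMLImportError",
    "ImportedModel",
    "to_sbml",
    "write_sbml",
    "read_sbml",
    "model_rhs_symbolic",
    "diff_rhs",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_SPECIES_IDS = ("p", "m_m", "m", "c")
_PARAM_IDS = ("sigma", "alpha", "delta", "k_t", "k_tl", "beta", "gamma", "k_b", "k_f")


_LOCAL_SYMBOLS = {name: sp.Symbol(name) for name in _PARAM_IDS + _SPECIES_IDS}


def _parse_law(law: str) -> sp.Expr:
    # plain symbol table: names like "gamma" must stay symbols, not functions
    return sp.sympify(law, locals=_LOCAL_SYMBOLS, rational=False)


class SBMLImportError(ValueError):
    """The document cannot be interpreted as a valid loop model."""


@dataclass(frozen=True)
class ImportedModel:
    """Parsed content of an SBML document."""

    params: ModelParameters
    initial_concentrations: dict[str, float]
    rhs: dict[str, sp.Expr]  # species id -> symbolic net rate
    variant: str | None  # recognised degradation variant, if any


# --- writing -----------------------------------------------------------------


def _reaction_table(variant: str) -> list[tuple[str, dict[str, int], str]]:
    """(id, net stoichiometry, kinetic law) for the ten channels."""
    gamma_complex = {"c": -1, "p": 1} if variant == "release" else {"c": -1}
    return [
        ("p53_production", {"p": 1}, "sigma"),
        ("p53_removal", {"p": -1}, "alpha * p"),
        ("complex_formation", {"p": -1, "m": -1, "c": 1}, "k_f * p * m"),
        ("complex_dissociation", {"p": 1, "m": 1, "c": -1}, "k_b * c"),
        ("p53_degradation_in_complex", {"c": -1, "m": 1}, "delta * c"),
        ("mdm2_degradation_in_complex", gamma_complex, "gamma * c"),
        ("transcription", {"m_m": 1}, "k_t * p**2"),
        ("mrna_decay", {"m_m": -1}, "beta * m_m"),
        ("translation", {"m": 1}, "k_tl * m_m"),
        ("mdm2_removal", {"m": -1}, "gamma * m"),
    ]


def _expr_to_mathml(expr: sp.Expr, parent: etree._Element) -> None:
    E = lambda tag: etree.SubElement(parent, f"{{{MATHML_NS}}}{tag}")  # noqa: E731
    if expr.is_Symbol:
        E("ci").text = f" {expr.name} "
        return
    if expr.is_Number:
        node = E("cn")
        if expr.is_Integer:
            node.set("type", "integer")
            node.text = f" {int(expr)} "
        else:
            node.text = f" {float(expr)!r} "
        return
    apply_el = E("apply")
    if expr.is_Add:
        op, args = "plus", expr.args
    elif expr.is_Mul:
        op, args = "times", expr.args
    elif expr.is_Pow:
        op, args = "power", expr.args
    else:
        raise ValueError(f"cannot serialize expression {expr}")
    etree.SubElement(apply_el, f"{{{MATHML_NS}}}{op}")
    for a in args:
        _expr_to_mathml(a, apply_el)


def to_sbml(
    params: ModelParameters,
    variant: str = "release",
    initial_concentrations: dict[str, float] | None = None,
) -> bytes:
    """Serialize the model to an SBML L3V2 document (UTF-8 bytes)."""
    if variant not in ("release", "codegradation"):
        raise ValueError(f"unknown variant {variant!r}")
    init = {sid: 0.0 for sid in _SPECIES_IDS}
    init.update(initial_concentrations or {})

    sbml = etree.Element(f"{{{SBML_NS}}}sbml", nsmap={None: SBML_NS})
    sbml.set("level", "3")
    sbml.set("version", "2")
    model = etree.SubElement(sbml, f"{{{SBML_NS}}}model")
    model.set("id", "p53_mdm2_negative_feedback_loop")
    model.set("substanceUnits", "nanomole")
    model.set("timeUnits", "hour")
    model.set("extentUnits", "nanomole")
    notes = etree.SubElement(model, f"{{{SBML_NS}}}notes")
    body = etree.SubElement(notes, "{http://www.w3.org/1999/xhtml}body")
    body.text = (
        "p53-Mdm2 negative feedback loop; concentrations in nM, time in "
        f"hours; complex degradation variant: {variant}."
    )

    units = etree.SubElement(model, f"{{{SBML_NS}}}listOfUnitDefinitions")
    for uid, kind, exp, scale, mult in (
        ("hour", "second", 1, 0, 3600.0),
        ("nanomole", "mole", 1, -9, 1.0),
    ):
        ud = etree.SubElement(units, f"{{{SBML_NS}}}unitDefinition")
        ud.set("id", uid)
        lou = etree.SubElement(ud, f"{{{SBML_NS}}}listOfUnits")
        u = etree.SubElement(lou, f"{{{SBML_NS}}}unit")
        u.set("kind", kind)
        u.set("exponent", str(exp))
        u.set("scale", str(scale))
        u.set("multiplier", repr(mult))

    comps = etree.SubElement(model, f"{{{SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(comps, f"{{{SBML_NS}}}compartment")
    comp.set("id", "nucleus")
    comp.set("size", "1")
    comp.set("spatialDimensions", "3")
    comp.set("constant", "true")

    species_el = etree.SubElement(model, f"{{{SBML_NS}}}listOfSpecies")
    for sid in _SPECIES_IDS:
        s = etree.SubElement(species_el, f"{{{SBML_NS}}}species")
        s.set("id", sid)
        s.set("compartment", "nucleus")
        s.set("initialConcentration", repr(float(init[sid])))
        s.set("hasOnlySubstanceUnits", "false")
        s.set("boundaryCondition", "false")
        s.set("constant", "false")

    params_el = etree.SubElement(model, f"{{{SBML_NS}}}listOfParameters")
    for pid in _PARAM_IDS:
        pel = etree.SubElement(params_el, f"{{{SBML_NS}}}parameter")
        pel.set("id", pid)
        pel.set("value", repr(float(getattr(params, pid))))
        pel.set("constant", "true")

    reactions_el = etree.SubElement(model, f"{{{SBML_NS}}}listOfReactions")
    for rid, stoich, law in _reaction_table(variant):
        r = etree.SubElement(reactions_el, f"{{{SBML_NS}}}reaction")
        r.set("id", rid)
        r.set("reversible", "false")
        reactants = {s: -n for s, n in stoich.items() if n < 0}
        products = {s: n for s, n in stoich.items() if n > 0}
        if reactants:
            lor = etree.SubElement(r, f"{{{SBML_NS}}}listOfReactants")
            for s, n in reactants.items():
                ref = etree.SubElement(lor, f"{{{SBML_NS}}}speciesReference")
                ref.set("species", s)
                ref.set("stoichiometry", str(n))
                ref.set("constant", "true")
        if products:
            lop = etree.SubElement(r, f"{{{SBML_NS}}}listOfProducts")
            for s, n in products.items():
                ref = etree.SubElement(lop, f"{{{SBML_NS}}}speciesReference")
                ref.set("species", s)
                ref.set("stoichiometry", str(n))
                ref.set("constant", "true")
        kl = etree.SubElement(r, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math")
        _expr_to_mathml(_parse_law(law), math)

    return etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def write_sbml(
    params: ModelParameters,
    path,
    variant: str = "release",
    initial_concentrations: dict[str, float] | None = None,
) -> None:
    with open(path, "wb") as fh:
        fh.write(to_sbml(params, variant, initial_concentrations))


# --- reading -----------------------------------------------------------------


def _mathml_to_expr(node: etree._Element) -> sp.Expr:
    tag = etree.QName(node).localname
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLImportError("math element must contain one expression")
        return _mathml_to_expr(children[0])
    if tag == "ci":
        return sp.Symbol(node.text.strip())
    if tag == "cn":
        return sp.Float(node.text.strip()) if "." in node.text or "e" in node.text.lower() else sp.Integer(int(node.text.strip()))
    if tag != "apply":
        raise SBMLImportError(f"unsupported MathML element <{tag}>")
    children = [c for c in node if isinstance(c.tag, str)]
    op = etree.QName(children[0]).localname
    args = [_mathml_to_expr(c) for c in children[1:]]
    if op == "times":
        return sp.Mul(*args)
    if op == "plus":
        return sp.Add(*args)
    if op == "minus":
        return args[0] - args[1] if len(args) == 2 else -args[0]
    if op == "divide":
        return args[0] / args[1]
    if op == "power":
        return args[0] ** args[1]
    raise SBMLImportError(f"unsupported MathML operator <{op}>")


def read_sbml(source) -> ImportedModel:
    """Parse an SBML document into parameters and symbolic net rates.

    ``source`` is a path, file-like or bytes.  Raises
    :class:`SBMLImportError` for negative rate constants (naming the
    parameter), unknown species or unsupported MathML.
    """
    if isinstance(source, (bytes, str)) and b"<" in (
        source if isinstance(source, bytes) else source.encode()
    ):
        root = etree.fromstring(source if isinstance(source, bytes) else source.encode())
    else:
        root = etree.parse(source).getroot()
    ns = {"s": SBML_NS, "m": MATHML_NS}
    model = root.find("s:model", ns)
    if model is None:
        raise SBMLImportError("document has no <model>")

    values: dict[str, float] = {}
    for pel in model.findall("s:listOfParameters/s:parameter", ns):
        pid, value = pel.get("id"), float(pel.get("value"))
        if pid in ("sigma",) and value < 0 or pid not in ("sigma",) and value <= 0:
            raise SBMLImportError(f"parameter {pid!r} has non-positive value {value}")
        values[pid] = value
    missing = [p for p in _PARAM_IDS if p not in values]
    if missing:
        raise SBMLImportError(f"missing parameters: {missing}")
    params = ModelParameters(**{p: values[p] for p in _PARAM_IDS})

    init: dict[str, float] = {}
    species_ids = []
    for sel in model.findall("s:listOfSpecies/s:species", ns):
        sid = sel.get("id")
        species_ids.append(sid)
        init[sid] = float(sel.get("initialConcentration", "0") or 0.0)
    unknown = set(species_ids) - set(_SPECIES_IDS)
    if unknown:
        raise SBMLImportError(f"unknown species: {sorted(unknown)}")

    net: dict[str, sp.Expr] = {sid: sp.Integer(0) for sid in _SPECIES_IDS}
    variant_probe = None
    for rel in model.findall("s:listOfReactions/s:reaction", ns):
        math = rel.find("s:kineticLaw/m:math", ns)
        if math is None:
            raise SBMLImportError(f"reaction {rel.get('id')!r} has no kinetic law")
        rate = _mathml_to_expr(math)
        for ref in rel.findall("s:listOfReactants/s:speciesReference", ns):
            net[ref.get("species")] -= float(ref.get("stoichiometry", "1")) * rate
        for ref in rel.findall("s:listOfProducts/s:speciesReference", ns):
            net[ref.get("species")] += float(ref.get("stoichiometry", "1")) * rate
        if rel.get("id") == "mdm2_degradation_in_complex":
            has_p = any(
                ref.get("species") == "p"
                for ref in rel.findall("s:listOfProducts/s:speciesReference", ns)
            )
            variant_probe = "release" if has_p else "codegradation"

    subs = {sp.Symbol(k): v for k, v in values.items()}
    rhs = {sid: sp.expand(expr.subs(subs)) for sid, expr in net.items()}
    return ImportedModel(
        params=params, initial_concentrations=init, rhs=rhs, variant=variant_probe
    )


def model_rhs_symbolic(params: ModelParameters, variant: str = "release") -> dict[str, sp.Expr]:
    """The package's own net rates with numeric rate constants, expanded."""
    table = _reaction_table(variant)
    subs = {sp.Symbol(pid): float(getattr(params, pid)) for pid in _PARAM_IDS}
    net = {sid: sp.Integer(0) for sid in _SPECIES_IDS}
    for _, stoich, law in table:
        rate = _parse_law(law)
        for sid, n in stoich.items():
            net[sid] += n * rate
    return {sid: sp.expand(expr.subs(subs)) for sid, expr in net.items()}


def diff_rhs(
    imported: ImportedModel,
    params: ModelParameters | None = None,
    variant: str | None = None,
    rel_tol: float = 1e-9,
) -> dict[str, list[str]]:
    """Term-level discrepancies between an imported model and this one.

    For every species, both net rates are expanded in the monomial basis
    of (p, m_m, m, c) and coefficients compared; terms whose coefficients
    disagree by more than ``rel_tol`` (relative to the larger magnitude)
    are reported as strings.  An empty dict means term-level agreement.
    """
    params = params or imported.params
    variant = variant or imported.variant or "release"
    expected = model_rhs_symbolic(params, variant)
    syms = sp.symbols("p m_m m c")
    report: dict[str, list[str]] = {}
    for sid in _SPECIES_IDS:
        diff_poly = sp.Poly(imported.rhs[sid] - expected[sid], *syms)
        exp_poly = sp.Poly(expected[sid], *syms)
        lines = []
        for monom, coeff in diff_poly.terms():
            ref = abs(exp_poly.as_dict().get(monom, 0.0))
            scale = max(float(ref), 1.0)
            if abs(float(coeff)) > rel_tol * scale:
                term = sp.Mul(sp.Float(float(coeff)), *[s**e for s, e in zip(syms, monom)])
                lines.append(f"extra/missing term {term}")
        if lines:
            report[sid] = lines
    return report
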