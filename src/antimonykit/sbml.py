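"""Bidirectional Antimony ↔ SBML Level 3 Version 1 (core) translation.

The Antimony side is this package's AST; the SBML side is XML built and read
with lxml.  Translation covers compartments, species (with compartment and
initial value), parameters, reactions (stoichiometry, reversibility from the
arrow kind, kinetic laws), assignment/rate rules, initial assignments,
events, function definitions, display names (SBML ``name`` attributes) and
MIRIAM CV-term annotations.  Comments cannot be represented in SBML; they
are dropped and itemized in the conversion report.  Modular-model
instantiations are flattened into a single core model (inner symbols
prefixed with the instance name) so the output needs no hierarchical
packages.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from lxml import etree

from .ast import AstNode, EMPTY_SPAN, SourceSpan
from .diagnostics import Diagnostic, Severity, run_diagnostics
from .mathml import MATHML_NS, expr_to_mathml, mathml_to_expr
from .parser import parse
from .render import render_math
from .symbols import MAIN_SCOPE, SymbolTable, build_symbol_table

SBML_L3V1_NS = "http://www.sbml.org/sbml/level3/version1/core"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"

DEFAULT_COMPARTMENT = "default_compartment"

# Antimony annotation keyword -> (namespace, element) of the biology qualifier
_QUALIFIER_TO_BQ = {
    "identity": "is",
    "hasPart": "hasPart",
    "part": "hasPart",
    "isPartOf": "isPartOf",
    "isVersionOf": "isVersionOf",
    "hasVersion": "hasVersion",
    "isHomologTo": "isHomologTo",
    "isDescribedBy": "isDescribedBy",
    "isEncodedBy": "isEncodedBy",
    "encodes": "encodes",
    "occursIn": "occursIn",
    "hasProperty": "hasProperty",
    "isPropertyOf": "isPropertyOf",
    "hasTaxon": "hasTaxon",
}
_BQ_TO_QUALIFIER = {"is": "identity"}
_BQ_TO_QUALIFIER.update({v: k for k, v in _QUALIFIER_TO_BQ.items() if k != "identity" and k != "part"})


class ConversionError(ValueError):
    """Conversion refused; carries the blocking diagnostics."""

    def __init__(self, message: str, diagnostics: list[Diagnostic] | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass
class ConversionReport:
    direction: str  # "ant->sbml" | "sbml->ant"
    lossy_items: list[tuple[Optional[SourceSpan], str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Antimony -> SBML
# ---------------------------------------------------------------------------

def antimony_to_sbml(ast: AstNode, model_id: str = "model") -> tuple[str, ConversionReport]:
    """Emit an SBML L3V1 core document for a parsed Antimony document.

    Refuses (raising :class:`ConversionError`) when the document carries
    error-severity diagnostics; warnings are allowed.
    """
    table = build_symbol_table(ast)
    diags = run_diagnostics(ast, table)
    errors = [d for d in diags if d.severity is Severity.ERROR]
    if errors:
        raise ConversionError(
            "document has error-severity diagnostics; fix them before converting",
            errors,
        )
    report = ConversionReport("ant->sbml")
    for comment in ast.find_all("comment"):
        report.lossy_items.append((comment.span, f"comment dropped: {comment.text}"))

    statements, chosen_name = _effective_statements(ast, table, report)
    flat_doc = AstNode("document", ast.span, statements)
    flat_table = build_symbol_table(flat_doc)

    xml = _emit_sbml(flat_doc, flat_table, chosen_name or model_id, report)
    return xml, report


def _effective_statements(
    ast: AstNode, table: SymbolTable, report: ConversionReport
) -> tuple[list[AstNode], Optional[str]]:
    """Top-level statements with modular-model calls flattened.

    A document whose only content is a single parameterless model definition
    is treated as that model (the common Antimony layout).
    """
    top = [c for c in ast.children if c.kind not in ("comment",)]
    model_defs = [c for c in top if c.kind == "modelDef"]
    rest = [c for c in top if c.kind != "modelDef"]
    if len(model_defs) == 1 and not model_defs[0].get("params") and not rest:
        inner = [c for c in model_defs[0].children if c.kind != "comment"]
        return _flatten(inner, table, report), model_defs[0].get("name")
    return _flatten(rest, table, report), None


def _flatten(statements: list[AstNode], table: SymbolTable, report: ConversionReport) -> list[AstNode]:
    out: list[AstNode] = []
    for stmt in statements:
        if stmt.kind == "modularCall":
            instance = stmt.get("name")
            info = table.models.get(stmt.get("model"))
            if info is None:
                continue
            scope = table.scopes[info.scope_name]
            mapping: dict[str, AstNode | str] = {}
            for formal, actual in zip(info.params, stmt.children):
                mapping[formal] = actual
            for local in scope.symbols:
                if local not in mapping:
                    mapping[local] = f"{instance}_{local}"
            body = info.node.children if info.node is not None else []
            for inner in body:
                if inner.kind == "comment":
                    continue
                renamed = _rename(inner, mapping)
                if renamed is not None:
                    out.append(renamed)
            report.warnings.append(
                f"modular call '{instance}' flattened into the main model"
            )
        elif stmt.kind == "modelDef":
            continue  # uninstantiated model definitions do not reach SBML
        else:
            out.append(stmt)
    return out


def _rename(node: AstNode, mapping: dict[str, AstNode | str]) -> AstNode:
    """Clone a subtree, renaming identifiers/targets per ``mapping``."""
    clone = AstNode(node.kind, node.span, text=node.text, attrs=dict(node.attrs))
    if node.kind == "identifier" and node.text in mapping:
        target = mapping[node.text]
        if isinstance(target, str):
            clone.text = target
        else:  # substitute actual-argument expression
            sub = target.children[0] if target.kind == "mathExpr" else target
            return _rename(sub, {})
    for key in ("name", "target", "compartment", "model"):
        val = clone.attrs.get(key)
        if isinstance(val, str) and val in mapping:
            tgt = mapping[val]
            clone.attrs[key] = tgt if isinstance(tgt, str) else render_math(tgt)
    if node.kind == "speciesRef" and node.text in mapping:
        tgt = mapping[node.text]
        clone.text = tgt if isinstance(tgt, str) else render_math(tgt)
    clone.children = [_rename(c, mapping) for c in node.children]
    return clone


def _emit_sbml(
    doc: AstNode, table: SymbolTable, model_id: str, report: ConversionReport
) -> str:
    nsmap = {None: SBML_L3V1_NS}
    sbml = etree.Element(f"{{{SBML_L3V1_NS}}}sbml", nsmap=nsmap)
    sbml.set("level", "3")
    sbml.set("version", "1")
    model = etree.SubElement(sbml, f"{{{SBML_L3V1_NS}}}model")
    model.set("id", _sanitize_id(model_id))

    scope = table.scopes[MAIN_SCOPE]
    species = [s for s in scope.symbols.values() if s.type == "species"]
    compartments = [s for s in scope.symbols.values() if s.type == "compartment"]
    parameters = [
        s for s in scope.symbols.values() if s.type == "parameter" and s.name != "time"
    ]

    need_default = any(s.compartment_of is None for s in species)

    def sub(parent, tag):
        return etree.SubElement(parent, f"{{{SBML_L3V1_NS}}}{tag}")

    # function definitions
    if table.functions:
        lof = sub(model, "listOfFunctionDefinitions")
        for fn in table.functions.values():
            fd = sub(lof, "functionDefinition")
            fd.set("id", fn.name)
            math = etree.SubElement(fd, f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
            lam = etree.SubElement(math, f"{{{MATHML_NS}}}lambda")
            for p in fn.params:
                bvar = etree.SubElement(lam, f"{{{MATHML_NS}}}bvar")
                ci = etree.SubElement(bvar, f"{{{MATHML_NS}}}ci")
                ci.text = p
            if fn.body is not None:
                body_math = expr_to_mathml(fn.body)
                lam.append(body_math[0])

    # compartments
    if compartments or need_default:
        loc = sub(model, "listOfCompartments")
        if need_default:
            c = sub(loc, "compartment")
            c.set("id", DEFAULT_COMPARTMENT)
            c.set("size", "1")
            c.set("constant", "true")
            c.set("spatialDimensions", "3")
        for sym in compartments:
            c = sub(loc, "compartment")
            c.set("id", sym.name)
            value = _literal_value(sym)
            if value is not None:
                c.set("size", value)
            c.set("constant", "false" if _has_dynamic_rule(sym) else "true")
            c.set("spatialDimensions", "3")
            _decorate(c, sym, report)

    # species
    if species:
        los = sub(model, "listOfSpecies")
        for sym in species:
            s = sub(los, "species")
            s.set("id", sym.name)
            s.set("compartment", sym.compartment_of or DEFAULT_COMPARTMENT)
            value = _literal_value(sym)
            if value is not None:
                s.set("initialConcentration", value)
            s.set("hasOnlySubstanceUnits", "false")
            s.set("boundaryCondition", "true" if sym.is_const else "false")
            s.set("constant", "false")
            _decorate(s, sym, report)

    # parameters
    if parameters:
        lop = sub(model, "listOfParameters")
        for sym in parameters:
            p = sub(lop, "parameter")
            p.set("id", sym.name)
            value = _literal_value(sym)
            if value is not None:
                p.set("value", value)
            p.set("constant", "false" if _has_dynamic_rule(sym) else "true")
            _decorate(p, sym, report)

    # initial assignments (non-literal '=' initializations)
    initial_assignments = []
    for sym in scope.symbols.values():
        if sym.type not in ("species", "parameter", "compartment"):
            continue
        last_assign = next(
            (e for e in reversed(sym.init_events) if e.kind == "assign"), None
        )
        if last_assign is not None and last_assign.value is not None:
            if _literal(last_assign.value) is None:
                initial_assignments.append((sym.name, last_assign.value))
    if initial_assignments:
        loi = sub(model, "listOfInitialAssignments")
        for name, value in initial_assignments:
            ia = sub(loi, "initialAssignment")
            ia.set("symbol", name)
            ia.append(expr_to_mathml(value))

    # rules
    rules = []
    for sym in scope.symbols.values():
        for ev in sym.init_events:
            if ev.kind == "rule":
                rules.append(("assignmentRule", sym.name, ev.value))
            elif ev.kind == "rate":
                rules.append(("rateRule", sym.name, ev.value))
    if rules:
        lor = sub(model, "listOfRules")
        for tag, name, value in rules:
            r = sub(lor, tag)
            r.set("variable", name)
            if value is not None:
                r.append(expr_to_mathml(value))

    # reactions
    if scope.reactions:
        lorx = sub(model, "listOfReactions")
        for i, rx in enumerate(scope.reactions):
            r = sub(lorx, "reaction")
            rid = rx.name or f"_J{i}"
            r.set("id", _sanitize_id(rid))
            r.set("reversible", "true" if rx.reversible else "false")
            r.set("fast", "false")
            rx_sym = scope.symbols.get(rx.name) if rx.name else None
            if rx_sym is not None:
                _decorate(r, rx_sym, report)
            if rx.reactants:
                lref = sub(r, "listOfReactants")
                for sname, stoich, _fixed in rx.reactants:
                    sr = sub(lref, "speciesReference")
                    sr.set("species", sname)
                    sr.set("stoichiometry", _fmt(stoich))
                    sr.set("constant", "true")
            if rx.products:
                lprod = sub(r, "listOfProducts")
                for sname, stoich, _fixed in rx.products:
                    sr = sub(lprod, "speciesReference")
                    sr.set("species", sname)
                    sr.set("stoichiometry", _fmt(stoich))
                    sr.set("constant", "true")
            if rx.law is not None:
                participant_names = {n for n, _, _ in rx.reactants + rx.products}
                modifiers = []
                for ident in rx.law.walk():
                    if ident.kind == "identifier":
                        sym = scope.symbols.get(ident.text or "")
                        if (
                            sym is not None
                            and sym.type == "species"
                            and ident.text not in participant_names
                            and ident.text not in modifiers
                        ):
                            modifiers.append(ident.text)
                if modifiers:
                    lmod = sub(r, "listOfModifiers")
                    for mname in modifiers:
                        mr = sub(lmod, "modifierSpeciesReference")
                        mr.set("species", mname)
                kl = sub(r, "kineticLaw")
                kl.append(expr_to_mathml(rx.law))

    # events
    event_nodes = [n for n in doc.children if n.kind == "eventStmt"]
    if event_nodes:
        loe = sub(model, "listOfEvents")
        for i, ev in enumerate(event_nodes):
            e = sub(loe, "event")
            e.set("id", _sanitize_id(ev.get("name") or f"_E{i}"))
            e.set("useValuesFromTriggerTime", "true")
            trig = sub(e, "trigger")
            trig.set("initialValue", "true")
            trig.set("persistent", "true")
            trig.append(expr_to_mathml(ev.children[0]))
            assigns = [c for c in ev.children[1:] if c.kind == "eventAssignment"]
            if assigns:
                loea = sub(e, "listOfEventAssignments")
                for a in assigns:
                    ea = sub(loea, "eventAssignment")
                    ea.set("variable", a.get("target"))
                    ea.append(expr_to_mathml(a.children[0]))

    etree.indent(sbml, space="  ")
    return etree.tostring(
        sbml, xml_declaration=True, encoding="UTF-8", pretty_print=False
    ).decode()


def _decorate(element: etree._Element, sym, report: ConversionReport) -> None:
    """Attach display name and CV-term annotations to an SBML element."""
    if sym.display_name:
        element.set("name", sym.display_name)
    if not sym.annotations:
        return
    metaid = f"metaid_{sym.name}"
    element.set("metaid", metaid)
    ann = etree.SubElement(element, f"{{{SBML_L3V1_NS}}}annotation")
    rdf = etree.SubElement(
        ann,
        f"{{{RDF_NS}}}RDF",
        nsmap={"rdf": RDF_NS, "bqbiol": BQBIOL_NS, "bqmodel": BQMODEL_NS},
    )
    desc = etree.SubElement(rdf, f"{{{RDF_NS}}}Description")
    desc.set(f"{{{RDF_NS}}}about", f"#{metaid}")
    by_qualifier: dict[str, list[str]] = {}
    for qualifier, uri in sym.annotations:
        bq = _QUALIFIER_TO_BQ.get(qualifier, "is")
        by_qualifier.setdefault(bq, []).append(uri)
    for bq, uris in by_qualifier.items():
        holder = etree.SubElement(desc, f"{{{BQBIOL_NS}}}{bq}")
        bag = etree.SubElement(holder, f"{{{RDF_NS}}}Bag")
        for uri in uris:
            li = etree.SubElement(bag, f"{{{RDF_NS}}}li")
            li.set(f"{{{RDF_NS}}}resource", uri)


def _literal(expr: AstNode) -> Optional[float]:
    node = expr
    while node.kind == "mathExpr":
        node = node.children[0]
    if node.kind == "number":
        return float(node.text or "0")
    if node.kind == "unaryOp" and node.text == "-":
        inner = _literal(node.children[0])
        return None if inner is None else -inner
    return None


def _literal_value(sym) -> Optional[str]:
    last_assign = next((e for e in reversed(sym.init_events) if e.kind == "assign"), None)
    if last_assign is None or last_assign.value is None:
        return None
    value = _literal(last_assign.value)
    return None if value is None else _fmt(value)


def _has_dynamic_rule(sym) -> bool:
    return sym.event_assigned or any(e.kind in ("rule", "rate") for e in sym.init_events)


def _fmt(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _sanitize_id(raw: str) -> str:
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in raw)
    if not out or out[0].isdigit():
        out = "_" + out
    return out


# ---------------------------------------------------------------------------
# SBML -> Antimony
# ---------------------------------------------------------------------------

def sbml_to_antimony(sbml_text: str) -> tuple[str, ConversionReport]:
    """Render an SBML document (L2 or L3 core) as Antimony source text.

    Non-core package constructs are skipped with a warning in the report;
    non-SBML XML raises :class:`ConversionError` naming the root element.
    """
    report = ConversionReport("sbml->ant")
    try:
        root = etree.fromstring(sbml_text.encode() if isinstance(sbml_text, str) else sbml_text)
    except etree.XMLSyntaxError as exc:
        raise ConversionError(f"input is not well-formed XML: {exc}") from exc
    if _local(root.tag) != "sbml":
        raise ConversionError(
            f"root element is <{_local(root.tag)}>, not an SBML document"
        )
    model = _child(root, "model")
    if model is None:
        raise ConversionError("SBML document contains no <model> element")

    core_ns = etree.QName(root.tag).namespace
    for el in root.iter():
        if not isinstance(el.tag, str):
            continue
        ns = etree.QName(el.tag).namespace
        if ns not in (core_ns, MATHML_NS, RDF_NS, BQBIOL_NS, BQMODEL_NS, None) and not str(
            ns
        ).startswith("http://www.w3.org/"):
            report.warnings.append(
                f"unsupported package element <{_local(el.tag)}> in namespace {ns} skipped"
            )

    lines: list[str] = []
    display_names: list[tuple[str, str]] = []
    annotations: list[tuple[str, str, str]] = []

    def harvest_meta(el: etree._Element, sid: str) -> None:
        name = el.get("name")
        if name:
            display_names.append((sid, name))
        for qualifier, uri in _cv_terms(el):
            annotations.append((sid, qualifier, uri))

    for c in _children(model, "listOfCompartments", "compartment"):
        sid = c.get("id")
        size = c.get("size") or c.get("volume")
        line = f"compartment {sid}"
        lines.append(line)
        if size is not None:
            lines.append(f"{sid} = {_clean_num(size)}")
        harvest_meta(c, sid)

    species_order: list[str] = []
    for s in _children(model, "listOfSpecies", "species"):
        sid = s.get("id")
        species_order.append(sid)
        boundary = s.get("boundaryCondition") == "true" or s.get("constant") == "true"
        decl = "const species " if boundary else "species "
        decl += ("$" if boundary else "") + sid
        comp = s.get("compartment")
        if comp:
            decl += f" in {comp}"
        lines.append(decl)
        init = s.get("initialConcentration") or s.get("initialAmount")
        if init is not None:
            lines.append(f"{sid} = {_clean_num(init)}")
        harvest_meta(s, sid)

    for p in _children(model, "listOfParameters", "parameter"):
        sid = p.get("id")
        value = p.get("value")
        if value is not None:
            lines.append(f"{sid} = {_clean_num(value)}")
        else:
            lines.append(f"{sid} = 0")
            report.warnings.append(f"parameter '{sid}' has no value; defaulted to 0")
        harvest_meta(p, sid)

    for ia in _children(model, "listOfInitialAssignments", "initialAssignment"):
        target = ia.get("symbol")
        math = _math_of(ia)
        if math is not None:
            lines.append(f"{target} = {render_math(math)}")

    for rule in _list_children(model, "listOfRules"):
        tag = _local(rule.tag)
        target = rule.get("variable")
        math = _math_of(rule)
        if math is None:
            continue
        if tag == "assignmentRule":
            lines.append(f"{target} := {render_math(math)}")
        elif tag == "rateRule":
            lines.append(f"{target}' = {render_math(math)}")
        elif tag == "algebraicRule":
            report.warnings.append("algebraic rule skipped (no Antimony equivalent)")

    for fd in _children(model, "listOfFunctionDefinitions", "functionDefinition"):
        fid = fd.get("id")
        math = _child(fd, "math", MATHML_NS)
        if math is None:
            continue
        lam = _child(math, "lambda", MATHML_NS)
        if lam is None:
            continue
        params = []
        body = None
        for child in lam:
            if not isinstance(child.tag, str):
                continue
            if _local(child.tag) == "bvar":
                ci = _child(child, "ci", MATHML_NS)
                params.append((ci.text or "").strip())
            else:
                body = child
        body_text = render_math(mathml_to_expr(body)) if body is not None else "0"
        lines.append(f"function {fid}({', '.join(params)})")
        lines.append(f"  {body_text}")
        lines.append("end")
        harvest_meta(fd, fid)

    for i, rx in enumerate(_children(model, "listOfReactions", "reaction")):
        rid = rx.get("id") or f"_J{i}"
        reversible = rx.get("reversible", "true") == "true"
        arrow = "->" if reversible else "=>"

        def side(list_tag: str) -> str:
            refs = []
            for sr in _children(rx, list_tag, "speciesReference"):
                stoich = float(sr.get("stoichiometry", "1"))
                prefix = "" if stoich == 1 else _fmt(stoich) + " "
                refs.append(prefix + sr.get("species"))
            return " + ".join(refs)

        lhs, rhs = side("listOfReactants"), side("listOfProducts")
        kl = _child(rx, "kineticLaw")
        law_text = None
        if kl is not None:
            math = _child(kl, "math", MATHML_NS)
            if math is not None:
                law_text = render_math(mathml_to_expr(math))
        line = f"{rid}: {lhs}{' ' if lhs else ''}{arrow}{' ' + rhs if rhs else ''}"
        if law_text:
            line += f"; {law_text}"
        lines.append(line)
        harvest_meta(rx, rid)

    for i, ev in enumerate(_children(model, "listOfEvents", "event")):
        eid = ev.get("id") or f"_E{i}"
        trig = _child(ev, "trigger")
        trig_math = _math_of(trig) if trig is not None else None
        if trig_math is None:
            report.warnings.append(f"event '{eid}' has no trigger math; skipped")
            continue
        assigns = []
        for ea in _children(ev, "listOfEventAssignments", "eventAssignment"):
            math = _math_of(ea)
            if math is not None:
                assigns.append(f"{ea.get('variable')} = {render_math(math)}")
        line = f"{eid}: at {render_math(trig_math)}"
        if assigns:
            line += ": " + ", ".join(assigns)
        lines.append(line)
        harvest_meta(ev, eid)

    model_id = model.get("id")
    if model_id:
        harvest_meta(model, model_id)

    for sid, name in display_names:
        lines.append(f'{sid} is "{name}"')
    for sid, qualifier, uri in annotations:
        lines.append(f'{sid} {qualifier} "{uri}"')

    text = "\n".join(lines) + ("\n" if lines else "")
    return text, report


def _local(tag) -> str:
    try:
        return etree.QName(tag).localname
    except ValueError:
        return str(tag)


def _child(el: etree._Element, name: str, ns: str | None = None):
    for c in el:
        if isinstance(c.tag, str) and _local(c.tag) == name:
            if ns is None or etree.QName(c.tag).namespace == ns:
                return c
    return None


def _children(el: etree._Element, list_name: str, item_name: str):
    lst = _child(el, list_name)
    if lst is None:
        return []
    return [c for c in lst if isinstance(c.tag, str) and _local(c.tag) == item_name]


def _list_children(el: etree._Element, list_name: str):
    lst = _child(el, list_name)
    if lst is None:
        return []
    return [c for c in lst if isinstance(c.tag, str)]


def _math_of(el: etree._Element):
    math = _child(el, "math", MATHML_NS)
    if math is None:
        return None
    return mathml_to_expr(math)


def _cv_terms(el: etree._Element):
    ann = _child(el, "annotation")
    if ann is None:
        return []
    out = []
    for desc in ann.iter(f"{{{RDF_NS}}}Description"):
        for holder in desc:
            if not isinstance(holder.tag, str):
                continue
            ns = etree.QName(holder.tag).namespace
            if ns not in (BQBIOL_NS, BQMODEL_NS):
                continue
            qualifier = _BQ_TO_QUALIFIER.get(_local(holder.tag), _local(holder.tag))
            for li in holder.iter(f"{{{RDF_NS}}}li"):
                uri = li.get(f"{{{RDF_NS}}}resource")
                if uri:
                    out.append((qualifier, uri))
    return out


def _clean_num(raw: str) -> str:
    try:
        return _fmt(float(raw))
    except ValueError:
        return raw


# ---------------------------------------------------------------------------
# semantic equivalence
# ---------------------------------------------------------------------------

def semantic_equivalent(a: str, b: str) -> tuple[bool, list[str]]:
    """Compare two Antimony documents as models, ignoring statement order.

    Species, compartments, parameters, reactions (participants,
    stoichiometry, reversibility), kinetic laws (commutativity-normalized),
    initial values, display names and annotations must all agree.  Returns
    ``(equal, differences)``; raises :class:`ConversionError` if either side
    has error-severity diagnostics.
    """
    summaries = []
    for label, text in (("a", a), ("b", b)):
        result = parse(text)
        table = build_symbol_table(result.ast)
        diags = run_diagnostics(result.ast, table, result.errors)
        errors = [d for d in diags if d.severity is Severity.ERROR]
        if errors:
            raise ConversionError(f"side '{label}' has blocking diagnostics", errors)
        summaries.append(_summarize(result.ast, table))
    sa, sb = summaries
    diffs: list[str] = []
    for section in sorted(set(sa) | set(sb)):
        va, vb = sa.get(section), sb.get(section)
        if va != vb:
            diffs.append(_describe_diff(section, va, vb))
    return (not diffs, diffs)


def _summarize(ast: AstNode, table: SymbolTable) -> dict:
    report = ConversionReport("ant->sbml")
    statements, _name = _effective_statements(ast, table, report)
    flat = build_symbol_table(AstNode("document", ast.span, statements))
    scope = flat.scopes[MAIN_SCOPE]
    out: dict[str, object] = {}
    species = {}
    parameters = {}
    compartments = {}
    for sym in scope.symbols.values():
        entry = {
            "init": _canon_opt(sym.init_value),
            "compartment": sym.compartment_of,
            "fixed": sym.is_const,
        }
        if sym.type == "species":
            species[sym.name] = entry
        elif sym.type == "parameter":
            parameters[sym.name] = {"init": entry["init"]}
        elif sym.type == "compartment":
            compartments[sym.name] = {"init": entry["init"]}
    # a species without a compartment lands in the implicit default
    # compartment on the SBML side; normalize so both phrasings compare equal
    for entry in species.values():
        if entry["compartment"] is None:
            entry["compartment"] = DEFAULT_COMPARTMENT
            compartments.setdefault(DEFAULT_COMPARTMENT, {"init": "1"})
    out["species"] = species
    out["parameters"] = parameters
    out["compartments"] = compartments

    reactions = {}
    for i, rx in enumerate(scope.reactions):
        key = rx.name or f"__anon{i}"
        reactions[key] = {
            "reactants": sorted((n, s) for n, s, _f in rx.reactants),
            "products": sorted((n, s) for n, s, _f in rx.products),
            "reversible": rx.reversible,
            "law": _canon_opt(rx.law),
        }
    out["reactions"] = reactions
    out["annotations"] = sorted(
        (sym.name, q, u)
        for sym in flat.all_symbols()
        for q, u in sym.annotations
    )
    out["display_names"] = sorted(
        (sym.name, sym.display_name)
        for sym in flat.all_symbols()
        if sym.display_name
    )
    return out


def _describe_diff(section: str, va, vb) -> str:
    if isinstance(va, dict) and isinstance(vb, dict):
        keys = set(va) | set(vb)
        for k in sorted(keys):
            if va.get(k) != vb.get(k):
                return (
                    f"{section} '{k}' differs: {va.get(k)!r} vs {vb.get(k)!r}"
                )
    return f"{section} differs: {va!r} vs {vb!r}"


def canonical_expr(expr: AstNode) -> str:
    """Commutativity-normalized string form of an expression tree."""
    node = expr
    while node.kind == "mathExpr":
        node = node.children[0]
    if node.kind == "number":
        return _fmt(float(node.text or "0"))
    if node.kind == "identifier":
        return node.text or ""
    if node.kind == "unaryOp":
        return f"({node.text} {canonical_expr(node.children[0])})"
    if node.kind == "call":
        args = " ".join(canonical_expr(a) for a in node.children)
        return f"({node.get('name')} {args})"
    if node.kind == "binaryOp":
        op = node.text or "?"
        if op in ("+", "*"):
            terms = sorted(_flatten_commutative(node, op))
            return f"({op} {' '.join(terms)})"
        return f"({op} {canonical_expr(node.children[0])} {canonical_expr(node.children[1])})"
    return f"<{node.kind}>"


def _flatten_commutative(node: AstNode, op: str) -> list[str]:
    terms: list[str] = []
    for child in node.children:
        c = child.children[0] if child.kind == "mathExpr" else child
        if c.kind == "binaryOp" and c.text == op:
            terms.extend(_flatten_commutative(c, op))
        else:
            terms.append(canonical_expr(c))
    return terms


def _canon_opt(expr: Optional[AstNode]) -> Optional[str]:
    return None if expr is None else canonical_expr(expr)


# ---------------------------------------------------------------------------
# paired-file synchronization
# ---------------------------------------------------------------------------

@dataclass
class SyncState:
    """Checksummed pairing of an ``.ant`` file and its ``.xml`` partner."""

    ant_path: str
    xml_path: str
    last_writer: Optional[str] = None  # "ant" | "xml"
    ant_checksum: Optional[str] = None
    xml_checksum: Optional[str] = None


def _checksum(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def sync_pair(
    state: SyncState, edited_side: str, new_text: str
) -> tuple[SyncState, ConversionReport]:
    """Propagate an edit on one side of an (.ant, .xml) pair to the other.

    A no-op when ``new_text`` matches the stored checksum for that side.  If
    conversion is refused (error diagnostics on the Antimony side), the
    partner file is left untouched and the refusal is reported.
    """
    if edited_side not in ("ant", "xml"):
        raise ValueError("edited_side must be 'ant' or 'xml'")
    checksum = _checksum(new_text)
    own_attr = f"{edited_side}_checksum"
    if getattr(state, own_attr) == checksum:
        report = ConversionReport(
            "ant->sbml" if edited_side == "ant" else "sbml->ant"
        )
        report.warnings.append("no-op: text unchanged since last sync")
        return state, report

    if edited_side == "ant":
        result = parse(new_text)
        try:
            partner_text, report = antimony_to_sbml(result.ast)
        except ConversionError as exc:
            report = ConversionReport("ant->sbml")
            report.warnings.append(f"propagation refused: {exc}")
            for d in exc.diagnostics:
                report.warnings.append(f"  blocking: [{d.rule_id}] {d.message}")
            return state, report
        Path(state.ant_path).write_text(new_text)
        Path(state.xml_path).write_text(partner_text)
        new_state = replace(
            state,
            last_writer="ant",
            ant_checksum=checksum,
            xml_checksum=_checksum(partner_text),
        )
        return new_state, report

    partner_text, report = sbml_to_antimony(new_text)
    Path(state.xml_path).write_text(new_text)
    Path(state.ant_path).write_text(partner_text)
    new_state = replace(
        state,
        last_writer="xml",
        xml_checksum=checksum,
        ant_checksum=_checksum(partner_text),
    )
    return new_state, report
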