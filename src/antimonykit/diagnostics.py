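"""Static error/warning catalog for Antimony models.

The rule registry distinguishes *errors* — problems that would prevent a
simulation from running (e.g. a parameter with no value) — from *warnings*,
which flag questionable modeling practice (e.g. silently overriding a
previously assigned value).  Rules are grouped by the model-element type they
concern: species (Spc), parameters (Prm), compartments (Cpt), reactions
(Rea), rate laws (Rl), events (Evt), functions (Fun), modular models (Mdl)
and general/grammar issues (Gen).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

from .ast import AstNode, SourceSpan

if TYPE_CHECKING:  # pragma: no cover
    from .symbols import SymbolTable


class Severity(enum.Enum):
    ERROR = "error"
    WARNING = "warning"


@dataclass(frozen=True)
class Rule:
    id: str
    category: str  # Spc Prm Cpt Rea Rl Evt Fun Mdl Gen
    severity: Severity
    description: str


@dataclass(frozen=True)
class Diagnostic:
    rule_id: str
    severity: Severity
    span: SourceSpan
    message: str

    def to_dict(self) -> dict:
        return {
            "rule": self.rule_id,
            "severity": self.severity.value,
            "line": self.span.line_start,
            "col": self.span.col_start,
            "endLine": self.span.line_end,
            "endCol": self.span.col_end,
            "message": self.message,
        }


_E = Severity.ERROR
_W = Severity.WARNING

_RULES = [
    Rule("SPC001", "Spc", _W, "No initial value"),
    Rule("SPC002", "Spc", _W, "Overriding previous value assignment"),
    Rule("PRM001", "Prm", _E, "No initial value"),
    Rule("PRM002", "Prm", _W, "Overriding previous value assignment"),
    Rule("CPT001", "Cpt", _W, "No initial value"),
    Rule("CPT002", "Cpt", _W, "Overriding previous value assignment"),
    Rule("REA001", "Rea", _W, "Referencing uninitialized species"),
    Rule("REA002", "Rea", _W, "Invalid arithmetic expression"),
    Rule("RL001", "Rl", _E, "Variable is not a fixed-species in reaction"),
    Rule("RL002", "Rl", _W, "Overriding rate rule"),
    Rule("EVT001", "Evt", _W, "Overriding defined event trigger"),
    Rule("FUN001", "Fun", _W, "Unused parameter"),
    Rule("FUN002", "Fun", _E, "Calling undefined function"),
    Rule("FUN003", "Fun", _E, "Incorrect function parameters"),
    Rule("FUN004", "Fun", _E, "Incorrect/incompatible parameter type"),
    Rule("FUN005", "Fun", _E, "Defining a new function with a used name"),
    Rule("MDL001", "Mdl", _E, "Calling undefined modular model"),
    Rule("MDL002", "Mdl", _E, "Incorrect modular model parameters"),
    Rule("MDL003", "Mdl", _E, "Incorrect parameter type"),
    Rule("GEN001", "Gen", _W, "Overriding display name"),
    Rule("GEN002", "Gen", _E, "Overriding incompatible type to previous type"),
    Rule("GEN003", "Gen", _E, "Unexpected token"),
    Rule("GEN004", "Gen", _E, "Unexpected newline or EOF"),
]

_RULE_INDEX = {r.id: r for r in _RULES}

# math functions understood without a user definition
BUILTIN_FUNCTIONS = frozenset(
    {
        "abs", "acos", "asin", "atan", "ceil", "cos", "cosh", "exp",
        "factorial", "floor", "ln", "log", "log10", "max", "min",
        "piecewise", "pow", "root", "sin", "sinh", "sqrt", "tan", "tanh",
    }
)


def rule_catalog() -> list[Rule]:
    """The full registry of diagnostic rules."""
    return list(_RULES)


def get_rule(rule_id: str) -> Rule:
    return _RULE_INDEX[rule_id]


def make(rule_id: str, span: SourceSpan, message: str) -> Diagnostic:
    rule = _RULE_INDEX[rule_id]
    return Diagnostic(rule_id, rule.severity, span, message)


# type-compatibility lattice for FUN004/MDL003: unknown is compatible with
# everything; species/parameter/compartment are mutually incompatible; the
# non-value tags (reaction, function, model, event, unit) are incompatible
# with any value slot.
_VALUE_TAGS = {"species", "parameter", "compartment"}


def _compatible(expected: str, actual: str) -> bool:
    if expected == "unknown" or actual == "unknown":
        return True
    if expected in _VALUE_TAGS and actual in _VALUE_TAGS:
        return expected == actual
    return expected == actual


def run_diagnostics(
    ast: AstNode,
    table: "SymbolTable",
    syntax_errors: Sequence[Diagnostic] = (),
) -> list[Diagnostic]:
    """Apply the full rule catalog to a parsed document and its symbol table.

    ``syntax_errors`` carries GEN003/GEN004 diagnostics from the parse step so
    the report covers the whole file.  Output is deterministic, ordered by
    (line, col, rule id), with one diagnostic per (rule, symbol, span).
    """
    diags: list[Diagnostic] = list(syntax_errors)
    gen002_spans: set[tuple] = set()

    # --- type-conflict rules (GEN002 / FUN005), evaluated first so later
    # rules can suppress cascades at the same span -------------------------
    for scope in table.scopes.values():
        for sym in scope.symbols.values():
            for tag, span, reason in sym.conflicts:
                if reason == "function-header":
                    diags.append(
                        make("FUN005", span,
                             f"'{sym.name}' is already used as a {sym.type}; "
                             f"cannot define a function with this name")
                    )
                else:
                    diags.append(
                        make("GEN002", span,
                             f"'{sym.name}' was a {sym.type} but is used here as a {tag}")
                    )
                    gen002_spans.add(_key(span))

    # --- initialization rules --------------------------------------------
    for scope in table.scopes.values():
        formals = set(scope.params)
        for sym in scope.symbols.values():
            if sym.name in formals:
                continue  # modular-model formals are bound at instantiation
            no_init = {"species": "SPC001", "parameter": "PRM001", "compartment": "CPT001"}
            override = {"species": "SPC002", "parameter": "PRM002", "compartment": "CPT002"}
            if sym.type in no_init and not sym.init_events:
                diags.append(
                    make(no_init[sym.type], sym.decl_span,
                         f"{sym.type} '{sym.name}' has no initial value")
                )
            if sym.type in override:
                assigns = [e for e in sym.init_events if e.kind in ("assign", "rule")]
                for ev in assigns[1:]:
                    diags.append(
                        make(override[sym.type], ev.span,
                             f"'{sym.name}' value assignment overrides a previous one")
                    )

    # --- rate-rule rules ---------------------------------------------------
    for scope in table.scopes.values():
        seen: dict[str, int] = {}
        for target, span in scope.rate_rules:
            seen[target] = seen.get(target, 0) + 1
            if seen[target] > 1:
                diags.append(
                    make("RL002", span, f"rate rule for '{target}' overrides a previous one")
                )
                continue
            sym = scope.symbols.get(target)
            if sym is None:
                continue
            if sym.type == "species" and sym.in_reaction and not sym.is_const:
                diags.append(
                    make("RL001", span,
                         f"'{target}' has a rate rule but participates in a reaction "
                         f"and is not a fixed species")
                )

    # --- event rules -------------------------------------------------------
    for scope in table.scopes.values():
        labels: set[str] = set()
        for name, span in scope.events:
            if name is None:
                continue
            if name in labels:
                diags.append(
                    make("EVT001", span, f"event '{name}' overrides a previously defined trigger")
                )
            labels.add(name)

    # --- reaction rules ----------------------------------------------------
    for scope in table.scopes.values():
        for rx in scope.reactions:
            if rx.law is None:
                continue
            flagged: set[str] = set()
            for ident in _identifiers(rx.law):
                name = ident.text
                sym = table.lookup(name, scope.name)
                if sym is None or name in flagged:
                    continue
                owner = table.scopes.get(sym.scope)
                if owner is not None and name in owner.params:
                    continue  # modular-model formals are bound at instantiation
                if sym.type == "species" and not sym.init_events:
                    diags.append(
                        make("REA001", rx.span,
                             f"kinetic law references uninitialized species '{name}'")
                    )
                    flagged.add(name)
                elif sym.type in ("reaction", "model", "event", "unit"):
                    if _key(ident.span) not in gen002_spans:
                        diags.append(
                            make("REA002", ident.span,
                                 f"'{name}' is a {sym.type} and cannot appear in an "
                                 f"arithmetic expression")
                        )
                        flagged.add(name)

    # --- function rules ----------------------------------------------------
    for fn in table.functions.values():
        used = {n.text for n in _identifiers(fn.body)} if fn.body is not None else set()
        for formal, span in zip(fn.params, fn.param_spans):
            if formal not in used:
                diags.append(
                    make("FUN001", span,
                         f"parameter '{formal}' of function '{fn.name}' is unused")
                )

    for scope in table.scopes.values():
        for call in scope.calls:
            name = call.get("name")
            fn = table.functions.get(name)
            if fn is None:
                if name not in BUILTIN_FUNCTIONS:
                    diags.append(
                        make("FUN002", call.span, f"call to undefined function '{name}'")
                    )
                continue
            if len(call.children) != len(fn.params):
                diags.append(
                    make("FUN003", call.span,
                         f"function '{name}' takes {len(fn.params)} argument(s), "
                         f"got {len(call.children)}")
                )
                continue
            for arg in call.children:
                ident = _bare_identifier(arg)
                if ident is None:
                    continue
                sym = table.lookup(ident.text, scope.name)
                if sym is None:
                    continue
                if sym.type not in _VALUE_TAGS and sym.type != "unknown":
                    if _key(ident.span) not in gen002_spans:
                        diags.append(
                            make("FUN004", ident.span,
                                 f"argument '{ident.text}' of '{name}' is a {sym.type}, "
                                 f"not a value")
                        )

    # --- modular-model rules ------------------------------------------------
    for scope in table.scopes.values():
        for mc in scope.modular_calls:
            model_name = mc.get("model")
            info = table.models.get(model_name)
            if info is None:
                diags.append(
                    make("MDL001", mc.span, f"call to undefined model '{model_name}'")
                )
                continue
            args = mc.children
            if len(args) != len(info.params):
                diags.append(
                    make("MDL002", mc.span,
                         f"model '{model_name}' takes {len(info.params)} parameter(s), "
                         f"got {len(args)}")
                )
                continue
            model_scope = table.scopes.get(info.scope_name)
            for formal, arg in zip(info.params, args):
                ident = _bare_identifier(arg)
                if ident is None:
                    continue
                actual_sym = table.lookup(ident.text, scope.name)
                actual = actual_sym.type if actual_sym else "unknown"
                expected = "unknown"
                if model_scope and formal in model_scope.symbols:
                    expected = model_scope.symbols[formal].type
                if not _compatible(expected, actual):
                    if _key(ident.span) not in gen002_spans:
                        diags.append(
                            make("MDL003", ident.span,
                                 f"argument '{ident.text}' is a {actual}; model "
                                 f"'{model_name}' expects a {expected} for '{formal}'")
                        )

    # --- display-name rule --------------------------------------------------
    for scope in table.scopes.values():
        for sym in scope.symbols.values():
            for span in sym.display_name_spans[1:]:
                diags.append(
                    make("GEN001", span, f"display name of '{sym.name}' overrides a previous one")
                )

    uniq: dict[tuple, Diagnostic] = {}
    for d in diags:
        uniq.setdefault((d.rule_id, _key(d.span), d.message), d)
    out = sorted(
        uniq.values(),
        key=lambda d: (d.span.line_start, d.span.col_start, d.rule_id),
    )
    return out


def _key(span: SourceSpan) -> tuple:
    return (span.line_start, span.col_start, span.line_end, span.col_end)


def _identifiers(expr: Optional[AstNode]) -> Iterable[AstNode]:
    if expr is None:
        return []
    out = []
    for node in expr.walk():
        if node.kind == "identifier":
            out.append(node)
    return out


def _bare_identifier(expr: AstNode) -> Optional[AstNode]:
    node = expr
    while node.kind == "mathExpr" and node.children:
        node = node.children[0]
    return node if node.kind == "identifier" else None


def to_json(diags: Iterable[Diagnostic]) -> str:
    return json.dumps([d.to_dict() for d in diags], indent=2)


def to_text(diags: Iterable[Diagnostic]) -> str:
    lines = []
    for d in diags:
        lines.append(
            f"{d.span.line_start + 1}:{d.span.col_start + 1}: "
            f"{d.severity.value} [{d.rule_id}] {d.message}"
        )
    return "\n".join(lines)
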