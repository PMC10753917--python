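"""Scoped symbol table for Antimony documents.

Every identifier in a document is classified by model-element type
(species, parameter, compartment, reaction, function, model, unit, event or
unknown) using structural evidence: appearing as a reactant/product or under
a ``species`` keyword makes a name a species; a ``compartment`` keyword or a
use after ``in`` makes it a compartment; reaction/event labels and
function/model headers type their names; a name only ever assigned or used
inside expressions defaults to parameter.  Evidence of two incompatible
*structural* types is recorded as a conflict (surfaced by the diagnostics
module), never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .ast import AstNode, SourceSpan
from .diagnostics import Diagnostic, make
from . import parser as _parser

MAIN_SCOPE = "__main"

# structural-evidence tags are mutually exclusive; weak evidence (assignment
# or use in an expression) merely defaults the type to parameter
_STRONG_TAGS = {"species", "compartment", "reaction", "function", "model", "unit", "event", "parameter"}


@dataclass
class InitEvent:
    kind: str  # assign | rule | rate
    span: SourceSpan
    value: Optional[AstNode]


@dataclass
class Symbol:
    name: str
    scope: str
    decl_span: SourceSpan
    strong_type: Optional[str] = None
    has_weak: bool = False
    init_events: list[InitEvent] = field(default_factory=list)
    compartment_of: Optional[str] = None
    annotations: list[tuple[str, str]] = field(default_factory=list)
    display_name: Optional[str] = None
    display_name_spans: list[SourceSpan] = field(default_factory=list)
    is_const: bool = False
    in_reaction: bool = False
    event_assigned: bool = False
    conflicts: list[tuple[str, SourceSpan, str]] = field(default_factory=list)

    @property
    def type(self) -> str:
        if self.strong_type:
            return self.strong_type
        return "parameter" if self.has_weak else "unknown"

    @property
    def init_spans(self) -> list[SourceSpan]:
        return [e.span for e in self.init_events]

    @property
    def init_value(self) -> Optional[AstNode]:
        for e in reversed(self.init_events):
            if e.value is not None:
                return e.value
        return None

    def add_strong(self, tag: str, span: SourceSpan, reason: str = "") -> None:
        if self.strong_type is None:
            self.strong_type = tag
        elif self.strong_type != tag:
            self.conflicts.append((tag, span, reason))

    def add_weak(self, span: SourceSpan) -> None:
        self.has_weak = True


@dataclass
class ReactionInfo:
    name: Optional[str]
    span: SourceSpan
    node: AstNode
    reactants: list[tuple[str, float, bool]]
    products: list[tuple[str, float, bool]]
    law: Optional[AstNode]
    reversible: bool


@dataclass
class FunctionInfo:
    name: str
    params: tuple[str, ...]
    param_spans: tuple[SourceSpan, ...]
    body: Optional[AstNode]
    span: SourceSpan
    name_span: SourceSpan


@dataclass
class ModelInfo:
    name: str
    params: tuple[str, ...]
    scope_name: str
    span: SourceSpan
    node: Optional[AstNode] = None


@dataclass
class Scope:
    name: str
    parent: Optional[str]
    symbols: dict[str, Symbol] = field(default_factory=dict)
    params: tuple[str, ...] = ()
    rate_rules: list[tuple[str, SourceSpan]] = field(default_factory=list)
    events: list[tuple[Optional[str], SourceSpan]] = field(default_factory=list)
    reactions: list[ReactionInfo] = field(default_factory=list)
    calls: list[AstNode] = field(default_factory=list)
    modular_calls: list[AstNode] = field(default_factory=list)


class SymbolTable:
    def __init__(self) -> None:
        self.scopes: dict[str, Scope] = {MAIN_SCOPE: Scope(MAIN_SCOPE, None)}
        self.functions: dict[str, FunctionInfo] = {}
        self.models: dict[str, ModelInfo] = {}
        self.import_paths: list[tuple[str, SourceSpan]] = []
        self.imports: dict[str, "SymbolTable"] = {}
        self.import_errors: list[Diagnostic] = []

    def scope_chain(self, scope_name: str):
        scope = self.scopes.get(scope_name)
        while scope is not None:
            yield scope
            scope = self.scopes.get(scope.parent) if scope.parent else None

    def lookup(self, name: str, scope_name: str = MAIN_SCOPE) -> Optional[Symbol]:
        for scope in self.scope_chain(scope_name):
            if name in scope.symbols:
                return scope.symbols[name]
        for sub in self.imports.values():
            hit = sub.lookup(name, MAIN_SCOPE)
            if hit is not None:
                return hit
        return None

    def all_symbols(self) -> list[Symbol]:
        out: list[Symbol] = []
        for scope in self.scopes.values():
            out.extend(scope.symbols.values())
        return out


def resolve_symbol(table: SymbolTable, name: str, scope: str = MAIN_SCOPE) -> Optional[Symbol]:
    """Innermost-first lookup of ``name`` starting at ``scope``."""
    if scope not in table.scopes:
        raise LookupError(f"unknown scope '{scope}'")
    return table.lookup(name, scope)


def build_symbol_table(ast: AstNode) -> SymbolTable:
    """Classify every identifier in a parsed document.

    Tolerates documents with syntax errors (faulty statements are simply
    absent from the tree).  Type-evidence conflicts are recorded on the
    symbol and surfaced later by the diagnostics module.
    """
    table = SymbolTable()
    _walk_statements(ast.children, table, MAIN_SCOPE)
    return table


def _sym(table: SymbolTable, scope_name: str, name: str, span: SourceSpan) -> Symbol:
    scope = table.scopes[scope_name]
    if name not in scope.symbols:
        scope.symbols[name] = Symbol(name, scope_name, span)
    return scope.symbols[name]


def _walk_statements(stmts: list[AstNode], table: SymbolTable, scope_name: str) -> None:
    for node in stmts:
        kind = node.kind
        if kind == "comment":
            continue
        if kind == "importStmt":
            table.import_paths.append((node.get("path"), node.span))
        elif kind == "modelDef":
            name = node.get("name")
            sym = _sym(table, scope_name, name, node.get("name_span"))
            sym.add_strong("model", node.get("name_span"), "model-header")
            child_scope = name
            if child_scope in table.scopes:  # duplicate model name: merge
                table.scopes[child_scope].parent = scope_name
            else:
                table.scopes[child_scope] = Scope(child_scope, scope_name)
            table.scopes[child_scope].params = node.get("params") or ()
            table.models[name] = ModelInfo(
                name, node.get("params") or (), child_scope, node.span, node
            )
            for p, ps in zip(node.get("params") or (), node.get("param_spans") or ()):
                _sym(table, child_scope, p, ps)
            _walk_statements(node.children, table, child_scope)
        elif kind == "functionDef":
            name = node.get("name")
            sym = _sym(table, scope_name, name, node.get("name_span"))
            sym.add_strong("function", node.get("name_span"), "function-header")
            body = node.children[0] if node.children else None
            table.functions[name] = FunctionInfo(
                name,
                node.get("params") or (),
                node.get("param_spans") or (),
                body,
                node.span,
                node.get("name_span"),
            )
        elif kind == "reactionStmt":
            _walk_reaction(node, table, scope_name)
        elif kind == "assignmentStmt":
            name = node.get("name")
            sym = _sym(table, scope_name, name, node.get("name_span"))
            sym.add_weak(node.get("name_span"))
            value = node.children[0] if node.children else None
            sym.init_events.append(
                InitEvent("rule" if node.get("rule") else "assign", node.span, value)
            )
            if value is not None:
                _walk_expr(value, table, scope_name)
        elif kind == "rateRuleStmt":
            name = node.get("name")
            sym = _sym(table, scope_name, name, node.get("name_span"))
            sym.add_weak(node.get("name_span"))
            value = node.children[0] if node.children else None
            sym.init_events.append(InitEvent("rate", node.span, value))
            table.scopes[scope_name].rate_rules.append((name, node.span))
            if value is not None:
                _walk_expr(value, table, scope_name)
        elif kind == "eventStmt":
            name = node.get("name")
            if name:
                sym = _sym(table, scope_name, name, node.get("name_span"))
                sym.add_strong("event", node.get("name_span"), "event-label")
            table.scopes[scope_name].events.append((name, node.span))
            for child in node.children:
                if child.kind == "mathExpr":
                    _walk_expr(child, table, scope_name)
                elif child.kind == "eventAssignment":
                    target = _sym(table, scope_name, child.get("target"), child.get("target_span"))
                    target.add_weak(child.get("target_span"))
                    target.event_assigned = True
                    if child.children:
                        _walk_expr(child.children[0], table, scope_name)
        elif kind == "varDecl":
            type_kw = node.get("type")
            for entry in node.children:
                name = entry.get("name")
                sym = _sym(table, scope_name, name, entry.get("name_span"))
                if type_kw == "species":
                    sym.add_strong("species", entry.get("name_span"), "species-keyword")
                elif type_kw == "compartment":
                    sym.add_strong("compartment", entry.get("name_span"), "compartment-keyword")
                elif type_kw == "formula":
                    sym.add_weak(entry.get("name_span"))
                if node.get("const") is True or entry.get("fixed"):
                    sym.is_const = True
                comp = entry.get("compartment")
                if comp:
                    sym.compartment_of = comp
                    csym = _sym(table, scope_name, comp, entry.get("name_span"))
                    csym.add_strong("compartment", entry.get("name_span"), "in-clause")
                if entry.children:
                    value = entry.children[0]
                    sym.init_events.append(InitEvent("assign", entry.span, value))
                    _walk_expr(value, table, scope_name)
        elif kind == "displayNameStmt":
            sym = _sym(table, scope_name, node.get("name"), node.get("name_span"))
            sym.display_name = node.get("display")
            sym.display_name_spans.append(node.span)
        elif kind == "annotationStmt":
            sym = _sym(table, scope_name, node.get("name"), node.get("name_span"))
            for uri in node.get("uris") or ():
                sym.annotations.append((node.get("qualifier"), uri))
        elif kind == "unitDecl":
            sym = _sym(table, scope_name, node.get("name"), node.get("name_span"))
            sym.add_strong("unit", node.get("name_span"), "unit-decl")
        elif kind == "modularCall":
            label = node.get("name")
            sym = _sym(table, scope_name, label, node.get("name_span"))
            sym.add_strong("model", node.get("name_span"), "modular-call")
            table.scopes[scope_name].modular_calls.append(node)
            for arg in node.children:
                _walk_expr(arg, table, scope_name)


def _walk_reaction(node: AstNode, table: SymbolTable, scope_name: str) -> None:
    name = node.get("name")
    if name:
        sym = _sym(table, scope_name, name, node.get("name_span"))
        sym.add_strong("reaction", node.get("name_span"), "reaction-label")
    reactants: list[tuple[str, float, bool]] = []
    products: list[tuple[str, float, bool]] = []
    law = None
    for child in node.children:
        if child.kind == "speciesRef":
            sname = child.text or ""
            ssym = _sym(table, scope_name, sname, child.get("name_span"))
            ssym.add_strong("species", child.get("name_span"), "reaction-participant")
            ssym.in_reaction = True
            if child.get("fixed"):
                ssym.is_const = True
            rec = (sname, child.get("stoichiometry", 1.0), bool(child.get("fixed")))
            (reactants if child.get("role") == "reactant" else products).append(rec)
        elif child.kind == "mathExpr":
            law = child
            _walk_expr(child, table, scope_name)
    table.scopes[scope_name].reactions.append(
        ReactionInfo(name, node.span, node, reactants, products, law, bool(node.get("reversible")))
    )


def _walk_expr(expr: AstNode, table: SymbolTable, scope_name: str) -> None:
    scope = table.scopes[scope_name]
    for node in expr.walk():
        if node.kind == "identifier":
            sym = _sym(table, scope_name, node.text or "", node.span)
            sym.add_weak(node.span)
        elif node.kind == "call":
            scope.calls.append(node)


class ImportError_(Exception):
    pass


def resolve_imports(
    ast: AstNode,
    loader: Callable[[str], str],
    _cache: Optional[dict] = None,
    _stack: Optional[tuple[str, ...]] = None,
) -> SymbolTable:
    """Build a symbol table with ``import`` statements resolved via ``loader``.

    ``loader`` maps an import path to Antimony text (raising on failure, e.g.
    ``FileNotFoundError``); imported files are parsed recursively, memoized so
    a file shared by two importers is loaded once, and cycles are reported
    once as an import error rather than recursing forever.
    """
    cache = _cache if _cache is not None else {}
    stack = _stack or ()
    table = build_symbol_table(ast)
    for path, span in table.import_paths:
        if path in stack:
            cycle = " -> ".join(stack[stack.index(path):] + (path,))
            table.import_errors.append(
                make("GEN003", span, f"import cycle detected: {cycle}")
            )
            continue
        if path in cache:
            table.imports[path] = cache[path]
            continue
        try:
            text = loader(path)
        except Exception as exc:
            table.import_errors.append(
                make("GEN003", span, f"cannot read import '{path}': {exc}")
            )
            continue
        result = _parser.parse(text)
        sub = resolve_imports(result.ast, loader, cache, stack + (path,))
        cache[path] = sub
        table.imports[path] = sub
        table.import_errors.extend(sub.import_errors)
    return table
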