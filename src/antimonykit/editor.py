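"""Editor-facing analysis primitives over (document, position).

All services are pure functions of the document text and a 0-based
(line, col) position: hover content, context-dependent completion,
go-to-definition, syntax-token classification and annotation coverage.
They are GUI-agnostic — an editor adapter decides how to display them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

from .ast import AstNode, Position, SourceSpan, node_at
from .lexer import ANNOTATION_QUALIFIERS, KEYWORDS, Token, tokenize
from .parser import parse
from .render import render_math
from .symbols import MAIN_SCOPE, Symbol, SymbolTable, build_symbol_table, resolve_imports


@dataclass
class HoverContent:
    symbol_name: str
    type_tag: str
    value_text: str
    compartment: Optional[str] = None
    annotations: list[str] = field(default_factory=list)
    signature: Optional[list[str]] = None
    display_name: Optional[str] = None
    preview: Optional[str] = None  # for import statements

    def text(self) -> str:
        """Stable plain-text key: value block."""
        lines = [f"name: {self.symbol_name}", f"type: {self.type_tag}"]
        if self.signature is not None:
            lines.append(f"signature: {self.symbol_name}({', '.join(self.signature)})")
        lines.append(f"value: {self.value_text}")
        if self.compartment:
            lines.append(f"compartment: {self.compartment}")
        if self.display_name:
            lines.append(f"display name: {self.display_name}")
        for uri in self.annotations:
            lines.append(f"annotation: {uri}")
        if self.preview:
            lines.append("preview:")
            lines.extend("  " + ln for ln in self.preview.splitlines())
        return "\n".join(lines)


@dataclass(frozen=True)
class CompletionItem:
    label: str
    type_tag: str
    detail: str


# context is derived solely from the token sequence left of the cursor
COMPLETION_CONTEXTS = ("reactant", "product", "kineticLaw", "assignmentRhs", "general")

_CONTEXT_TYPES = {
    "reactant": ("species",),
    "product": ("species",),
    "kineticLaw": ("species", "parameter", "compartment", "function"),
    "assignmentRhs": ("species", "parameter", "compartment", "function"),
    "general": (
        "species",
        "parameter",
        "compartment",
        "reaction",
        "function",
        "model",
        "event",
        "unit",
        "unknown",
    ),
}


@dataclass
class AnnotationCoverage:
    annotated: list[str]
    unannotated: list[str]
    mode: str  # "highlight-annotated" | "highlight-unannotated"

    def highlighted(self) -> list[str]:
        return self.annotated if self.mode == "highlight-annotated" else self.unannotated


def _analyze(document: str) -> tuple[AstNode, SymbolTable]:
    result = parse(document)
    return result.ast, build_symbol_table(result.ast)


def _scope_at(ast: AstNode, position: Position) -> str:
    scope = MAIN_SCOPE
    node = ast
    while True:
        nxt = None
        for child in node.children:
            if child.span.contains(*position):
                nxt = child
                break
        if nxt is None:
            return scope
        if nxt.kind == "modelDef":
            scope = nxt.get("name")
        node = nxt


def _name_token_at(document: str, position: Position) -> Optional[Token]:
    line, col = position
    for tok in tokenize(document):
        if tok.kind == "NAME" and tok.span.contains(line, col):
            return tok
    return None


def hover(
    document: str,
    position: Position,
    loader: Optional[Callable[[str], str]] = None,
) -> Optional[HoverContent]:
    """Hover text for the symbol under ``position``, or None off-symbol.

    On an import statement the hover is a preview of the imported file's
    top-level symbols (requires a ``loader`` mapping path -> text).
    """
    ast, table = _analyze(document)
    import_node = _import_at(ast, position)
    if import_node is not None:
        path = import_node.get("path")
        preview = f'import "{path}"'
        if loader is not None:
            try:
                sub = resolve_imports(ast, loader)
                imported = sub.imports.get(path)
                if imported is not None:
                    names = [
                        f"{s.name}: {s.type}"
                        for s in imported.scopes[MAIN_SCOPE].symbols.values()
                    ]
                    names.extend(f"{f}: function" for f in imported.functions
                                 if f not in imported.scopes[MAIN_SCOPE].symbols)
                    preview = "\n".join(names) or "(empty file)"
            except Exception:
                pass
        return HoverContent(
            symbol_name=path,
            type_tag="import",
            value_text="imported file",
            preview=preview,
        )

    tok = _name_token_at(document, position)
    if tok is None or tok.text in KEYWORDS:
        return None
    if loader is not None:
        table = resolve_imports(ast, loader)
    scope = _scope_at(ast, position)
    sym = table.lookup(tok.text, scope)
    if sym is None:
        return None
    return _hover_for_symbol(sym, table)


def _hover_for_symbol(sym: Symbol, table: SymbolTable) -> HoverContent:
    value = "uninitialized"
    if sym.init_value is not None:
        value = render_math(sym.init_value)
    signature = None
    fn = table.functions.get(sym.name)
    if sym.type == "function" and fn is not None:
        signature = list(fn.params)
    return HoverContent(
        symbol_name=sym.name,
        type_tag=sym.type,
        value_text=value,
        compartment=sym.compartment_of,
        annotations=[uri for _q, uri in sym.annotations],
        signature=signature,
        display_name=sym.display_name,
    )


def _parent_of(root: AstNode, target: AstNode) -> Optional[AstNode]:
    for node in root.walk():
        if target in node.children:
            return node
    return None


def _import_at(ast: AstNode, position: Position) -> Optional[AstNode]:
    node = node_at(ast, position)
    while node is not None:
        if node.kind == "importStmt":
            return node
        node = _parent_of(ast, node)
    return None


def completion_context(document: str, position: Position) -> tuple[str, str]:
    """(context, prefix) derived from the tokens left of the cursor."""
    line, col = position
    lines = document.split("\n")
    text_before = lines[line][:col] if line < len(lines) else ""
    # identifier chars immediately left of the cursor form the prefix
    i = len(text_before)
    while i > 0 and (text_before[i - 1].isalnum() or text_before[i - 1] == "_"):
        i -= 1
    prefix = text_before[i:]
    before = text_before[:i]
    toks = [t for t in tokenize(before) if t.kind not in ("NEWLINE", "EOF", "COMMENT")]
    texts = [t.text for t in toks]
    if "->" in texts or "=>" in texts:
        arrow_idx = max(
            (j for j, t in enumerate(texts) if t in ("->", "=>")), default=-1
        )
        if ";" in texts[arrow_idx + 1 :]:
            return "kineticLaw", prefix
        return "product", prefix
    if ":=" in texts or "=" in texts:
        return "assignmentRhs", prefix
    if "+" in texts or "$" in texts or (texts and texts[-1] == ":"):
        return "reactant", prefix
    return "general", prefix


def complete(
    document: str,
    position: Position,
    loader: Optional[Callable[[str], str]] = None,
) -> list[CompletionItem]:
    """Context-dependent, prefix-filtered completion candidates.

    Reactant/product positions admit only species; rate-law and assignment
    positions admit species, parameters, compartments and functions; ordering
    is type priority for the context, then lexicographic; prefix matching is
    case-sensitive.  Pass ``loader`` to include symbols from imported files.
    """
    ast, table = _analyze(document)
    if loader is not None:
        table = resolve_imports(ast, loader)
    context, prefix = completion_context(document, position)
    scope = _scope_at(ast, position)
    admitted = _CONTEXT_TYPES[context]

    candidates: dict[str, Symbol] = {}
    for sc in table.scope_chain(scope):
        for name, sym in sc.symbols.items():
            candidates.setdefault(name, sym)
    for sub in table.imports.values():
        for name, sym in sub.scopes[MAIN_SCOPE].symbols.items():
            candidates.setdefault(name, sym)

    line, col = position
    items = []
    for name, sym in candidates.items():
        if not name.startswith(prefix):
            continue
        if sym.type not in admitted:
            continue
        # the partially typed word itself is not a suggestion
        if name == prefix and sym.decl_span.contains(line, max(col - 1, 0)):
            continue
        priority = admitted.index(sym.type)
        detail = sym.type
        if sym.display_name:
            detail += f' "{sym.display_name}"'
        items.append((priority, name, CompletionItem(name, sym.type, detail)))
    items.sort(key=lambda t: (t[0], t[1]))
    return [it for _p, _n, it in items]


def goto_definition(document: str, position: Position) -> list[SourceSpan]:
    """Spans of the declaration (first) and, when distinct, the initialization
    of the symbol under ``position``; empty when not on a symbol."""
    ast, table = _analyze(document)
    tok = _name_token_at(document, position)
    if tok is None or tok.text in KEYWORDS:
        return []
    scope = _scope_at(ast, position)
    sym = table.lookup(tok.text, scope)
    if sym is None:
        return []
    targets = [sym.decl_span]
    for span in sym.init_spans:
        if span != sym.decl_span:
            targets.append(span)
            break
    return targets


_TYPE_TO_CLASS = {
    "species": "speciesName",
    "parameter": "parameterName",
    "compartment": "compartmentName",
    "reaction": "reactionName",
    "event": "eventName",
    "function": "functionName",
    "unit": "unit",
    "model": "modelName",
    "unknown": "parameterName",
}


def classify_tokens(document: str) -> list[tuple[SourceSpan, str]]:
    """Classify every non-whitespace token for syntax highlighting.

    Classes: reactionName, speciesName, parameterName, compartmentName,
    operator, eventName, unit, functionName, keyword, number, comment,
    annotationKeyword, modelName, string.
    """
    ast, table = _analyze(document)
    toks = tokenize(document)
    out: list[tuple[SourceSpan, str]] = []
    for i, tok in enumerate(toks):
        if tok.kind == "EOF" or tok.kind == "NEWLINE":
            continue
        if tok.kind == "COMMENT":
            out.append((tok.span, "comment"))
        elif tok.kind == "NUMBER":
            out.append((tok.span, "number"))
        elif tok.kind == "STRING":
            out.append((tok.span, "string"))
        elif tok.kind in ("OP", "ERROR"):
            out.append((tok.span, "operator"))
        elif tok.kind == "NAME":
            nxt = toks[i + 1] if i + 1 < len(toks) else None
            if tok.text in ANNOTATION_QUALIFIERS and nxt is not None and nxt.kind == "STRING":
                out.append((tok.span, "annotationKeyword"))
                continue
            if tok.text in KEYWORDS:
                out.append((tok.span, "keyword"))
                continue
            scope = _scope_at(ast, (tok.line, tok.col))
            sym = table.lookup(tok.text, scope)
            cls = _TYPE_TO_CLASS.get(sym.type if sym else "unknown", "parameterName")
            if sym is None and tok.text in table.functions:
                cls = "functionName"
            out.append((tok.span, cls))
    return out


def annotation_coverage(document: str, mode: str = "highlight-unannotated") -> AnnotationCoverage:
    """Partition annotatable elements (species, reactions, compartments) by
    whether they carry at least one annotation statement."""
    if mode not in ("highlight-annotated", "highlight-unannotated"):
        raise ValueError(f"unknown mode '{mode}'")
    _ast, table = _analyze(document)
    annotated: list[str] = []
    unannotated: list[str] = []
    for sym in table.all_symbols():
        if sym.type not in ("species", "reaction", "compartment"):
            continue
        (annotated if sym.annotations else unannotated).append(sym.name)
    return AnnotationCoverage(sorted(annotated), sorted(unannotated), mode)
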