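"""Typed syntax tree for Antimony documents.

Every node carries a :class:`SourceSpan` mapping it back to the source text,
using 0-based line/column coordinates with half-open column ranges (the
convention of mainstream editor protocols).  Statement-level node kinds:

``document``, ``modelDef``, ``reactionStmt``, ``speciesRef``,
``assignmentStmt``, ``rateRuleStmt``, ``eventStmt``, ``functionDef``,
``modularCall``, ``importStmt``, ``annotationStmt``, ``displayNameStmt``,
``unitDecl``, ``varDecl``, ``comment`` and ``mathExpr``.  Inside a
``mathExpr`` wrapper the expression tree uses ``binaryOp``, ``unaryOp``,
``call``, ``identifier`` and ``number`` nodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator, Optional, Tuple

Position = Tuple[int, int]


@dataclass(frozen=True)
class SourceSpan:
    """Half-open region of source text: lines are 0-based, columns half-open."""

    line_start: int
    col_start: int
    line_end: int
    col_end: int

    def contains(self, line: int, col: int) -> bool:
        return (self.line_start, self.col_start) <= (line, col) < (self.line_end, self.col_end)

    def start(self) -> Position:
        return (self.line_start, self.col_start)

    def end(self) -> Position:
        return (self.line_end, self.col_end)

    def cover(self, other: "SourceSpan") -> "SourceSpan":
        """Smallest span containing both self and other."""
        lo = min(self.start(), other.start())
        hi = max(self.end(), other.end())
        return SourceSpan(lo[0], lo[1], hi[0], hi[1])

    def slice(self, text: str) -> str:
        """Extract the lexical extent of this span from the source text."""
        lines = text.split("\n")
        if self.line_start == self.line_end:
            return lines[self.line_start][self.col_start : self.col_end]
        parts = [lines[self.line_start][self.col_start :]]
        parts.extend(lines[self.line_start + 1 : self.line_end])
        parts.append(lines[self.line_end][: self.col_end])
        return "\n".join(parts)


EMPTY_SPAN = SourceSpan(0, 0, 0, 0)

STATEMENT_KINDS = frozenset(
    {
        "modelDef",
        "reactionStmt",
        "assignmentStmt",
        "rateRuleStmt",
        "eventStmt",
        "functionDef",
        "modularCall",
        "importStmt",
        "annotationStmt",
        "displayNameStmt",
        "unitDecl",
        "varDecl",
        "comment",
    }
)


@dataclass
class AstNode:
    kind: str
    span: SourceSpan
    children: list["AstNode"] = field(default_factory=list)
    text: Optional[str] = None
    attrs: dict[str, Any] = field(default_factory=dict)

    def walk(self) -> Iterator["AstNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def find_all(self, kind: str) -> Iterator["AstNode"]:
        return (n for n in self.walk() if n.kind == kind)

    def get(self, key: str, default: Any = None) -> Any:
        return self.attrs.get(key, default)


def structurally_equal(a: AstNode, b: AstNode) -> bool:
    """AST equality ignoring spans (and span-valued attributes)."""
    if a.kind != b.kind or a.text != b.text:
        return False
    ka = {k: v for k, v in a.attrs.items() if not isinstance(v, SourceSpan)}
    kb = {k: v for k, v in b.attrs.items() if not isinstance(v, SourceSpan)}
    if ka != kb:
        return False
    if len(a.children) != len(b.children):
        return False
    return all(structurally_equal(x, y) for x, y in zip(a.children, b.children))


def node_at(ast: AstNode, position: Position) -> Optional[AstNode]:
    """Deepest node whose span contains ``position`` (0-based line/col)."""
    line, col = position
    if not ast.span.contains(line, col):
        return None
    best = ast
    # children spans are disjoint, so a simple descent suffices
    while True:
        nxt = None
        for child in best.children:
            if child.span.contains(line, col):
                nxt = child
                break
        if nxt is None:
            return best
        best = nxt
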