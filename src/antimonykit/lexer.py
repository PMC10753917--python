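"""Tokenizer for Antimony source text.

Produces a flat token stream with spans; comments are kept as tokens so the
parser can preserve them and the syntax highlighter can classify them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .ast import SourceSpan

# order matters: longest operators first
_OPERATORS = [
    "->",
    "=>",
    ":=",
    "==",
    "!=",
    ">=",
    "<=",
    "&&",
    "||",
    "+",
    "-",
    "*",
    "/",
    "^",
    "(",
    ")",
    ",",
    ";",
    ":",
    "=",
    "<",
    ">",
    "'",
    "$",
    "!",
]

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_NUMBER_RE = re.compile(r"(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")
_STRING_RE = re.compile(r'"([^"\\]|\\.)*"')

KEYWORDS = frozenset(
    {
        "const",
        "var",
        "species",
        "compartment",
        "formula",
        "function",
        "model",
        "module",
        "end",
        "import",
        "at",
        "unit",
        "is",
        "in",
        "has",
    }
)

# MIRIAM-style annotation qualifiers accepted in annotation statements
ANNOTATION_QUALIFIERS = frozenset(
    {
        "identity",
        "hasPart",
        "part",
        "isPartOf",
        "isVersionOf",
        "hasVersion",
        "isHomologTo",
        "isDescribedBy",
        "isEncodedBy",
        "encodes",
        "occursIn",
        "hasProperty",
        "isPropertyOf",
        "hasTaxon",
        "origin",
    }
)


@dataclass(frozen=True)
class Token:
    kind: str  # NAME NUMBER STRING OP NEWLINE COMMENT ERROR EOF
    text: str
    line: int
    col: int
    line_end: int
    col_end: int

    @property
    def span(self) -> SourceSpan:
        return SourceSpan(self.line, self.col, self.line_end, self.col_end)


def tokenize(text: str) -> list[Token]:
    tokens: list[Token] = []
    line = 0
    col = 0
    i = 0
    n = len(text)

    def emit(kind: str, lexeme: str, l0: int, c0: int, l1: int, c1: int) -> None:
        tokens.append(Token(kind, lexeme, l0, c0, l1, c1))

    while i < n:
        ch = text[i]
        if ch == "\n":
            emit("NEWLINE", "\n", line, col, line, col + 1)
            i += 1
            line += 1
            col = 0
            continue
        if ch in " \t\r":
            i += 1
            col += 1
            continue
        if text.startswith("//", i):
            j = text.find("\n", i)
            j = n if j == -1 else j
            emit("COMMENT", text[i:j], line, col, line, col + (j - i))
            col += j - i
            i = j
            continue
        if text.startswith("/*", i):
            j = text.find("*/", i + 2)
            j = n - 2 if j == -1 else j
            lexeme = text[i : j + 2]
            l0, c0 = line, col
            nl = lexeme.count("\n")
            if nl:
                line += nl
                col = len(lexeme) - lexeme.rfind("\n") - 1
            else:
                col += len(lexeme)
            emit("COMMENT", lexeme, l0, c0, line, col)
            i = j + 2
            continue
        m = _NAME_RE.match(text, i)
        if m:
            emit("NAME", m.group(), line, col, line, col + len(m.group()))
            col += len(m.group())
            i = m.end()
            continue
        m = _NUMBER_RE.match(text, i)
        if m:
            emit("NUMBER", m.group(), line, col, line, col + len(m.group()))
            col += len(m.group())
            i = m.end()
            continue
        m = _STRING_RE.match(text, i)
        if m:
            emit("STRING", m.group(), line, col, line, col + len(m.group()))
            col += len(m.group())
            i = m.end()
            continue
        for op in _OPERATORS:
            if text.startswith(op, i):
                emit("OP", op, line, col, line, col + len(op))
                col += len(op)
                i += len(op)
                break
        else:
            emit("ERROR", ch, line, col, line, col + 1)
            i += 1
            col += 1
    tokens.append(Token("EOF", "", line, col, line, col))
    return tokens
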