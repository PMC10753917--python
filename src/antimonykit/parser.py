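"""Recursive-descent parser for the Antimony modeling language.

Covers the statement subset a reaction-network modeler uses day to day:
reactions (with ``->`` reversible and ``=>`` irreversible arrows), constant
and variable declarations with ``species``/``compartment``/``formula`` type
keywords, value assignments (``=``), assignment rules (``:=``), rate rules
(``X' = ...``), events (``at``), function definitions, model/module blocks,
modular-model instantiation, imports, annotation statements, display names
(``is "..."``) and unit declarations.  Grammar violations never raise: they
become GEN-category diagnostics and parsing resumes at the next statement
boundary, so every error in a file is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ast import AstNode, SourceSpan, EMPTY_SPAN
from .diagnostics import Diagnostic, make
from .lexer import ANNOTATION_QUALIFIERS, Token, tokenize


@dataclass
class ParseResult:
    ast: AstNode
    errors: list[Diagnostic] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


class _SyntaxError(Exception):
    def __init__(self, span: SourceSpan, message: str, at_end: bool):
        super().__init__(message)
        self.span = span
        self.message = message
        self.at_end = at_end  # True -> GEN004 (newline/EOF), else GEN003


def parse(text: str) -> ParseResult:
    """Parse Antimony source text; never raises."""
    return _Parser(tokenize(text)).parse_document()


class _Parser:
    def __init__(self, tokens: list[Token]):
        self.tokens = tokens
        self.pos = 0
        self.errors: list[Diagnostic] = []

    # --- token helpers ----------------------------------------------------
    def peek(self, offset: int = 0) -> Token:
        i = min(self.pos + offset, len(self.tokens) - 1)
        return self.tokens[i]

    def advance(self) -> Token:
        tok = self.tokens[self.pos]
        if tok.kind != "EOF":
            self.pos += 1
        return tok

    def at(self, kind: str, text: str | None = None) -> bool:
        tok = self.peek()
        return tok.kind == kind and (text is None or tok.text == text)

    def expect(self, kind: str, text: str | None = None) -> Token:
        tok = self.peek()
        if tok.kind == kind and (text is None or tok.text == text):
            return self.advance()
        want = text or kind.lower()
        if tok.kind in ("NEWLINE", "EOF"):
            raise _SyntaxError(tok.span, f"unexpected {'newline' if tok.kind == 'NEWLINE' else 'end of file'}, expected '{want}'", True)
        raise _SyntaxError(tok.span, f"unexpected token '{tok.text}', expected '{want}'", False)

    def skip_newlines(self, node_sink: list[AstNode] | None = None) -> None:
        while True:
            if self.at("NEWLINE") or self.at("OP", ";"):
                self.advance()
            elif self.at("COMMENT"):
                tok = self.advance()
                if node_sink is not None:
                    node_sink.append(AstNode("comment", tok.span, text=tok.text))
            else:
                return

    def end_statement(self) -> None:
        """Consume the statement terminator (newline, ';', EOF or 'end')."""
        tok = self.peek()
        if tok.kind in ("NEWLINE", "EOF") or (tok.kind == "OP" and tok.text == ";"):
            if tok.kind != "EOF":
                self.advance()
            return
        if tok.kind == "COMMENT" or (tok.kind == "NAME" and tok.text == "end"):
            return
        raise _SyntaxError(tok.span, f"unexpected token '{tok.text}' at end of statement", False)

    def recover(self) -> None:
        """Skip to the next statement boundary after a syntax error."""
        while not self.at("EOF"):
            tok = self.peek()
            if tok.kind == "NEWLINE" or (tok.kind == "OP" and tok.text == ";"):
                self.advance()
                return
            if tok.kind == "NAME" and tok.text == "end":
                return
            self.advance()

    def error(self, exc: _SyntaxError) -> None:
        rule = "GEN004" if exc.at_end else "GEN003"
        self.errors.append(make(rule, exc.span, exc.message))

    # --- document ---------------------------------------------------------
    def parse_document(self) -> ParseResult:
        children: list[AstNode] = []
        self.skip_newlines(children)
        while not self.at("EOF"):
            try:
                stmt = self.parse_statement()
                if stmt is not None:
                    children.append(stmt)
            except _SyntaxError as exc:
                self.error(exc)
                self.recover()
            if self.at("NAME", "end"):
                tok = self.advance()
                self.errors.append(make("GEN003", tok.span, "unexpected 'end' outside a block"))
            self.skip_newlines(children)
        span = EMPTY_SPAN
        if children:
            span = children[0].span
            for c in children[1:]:
                span = span.cover(c.span)
        doc = AstNode("document", span, children)
        return ParseResult(doc, self.errors)

    # --- statements ---------------------------------------------------------
    def parse_statement(self) -> AstNode | None:
        tok = self.peek()
        if tok.kind == "COMMENT":
            self.advance()
            return AstNode("comment", tok.span, text=tok.text)
        if tok.kind == "NAME":
            word = tok.text
            if word == "import":
                return self.parse_import()
            if word == "function":
                return self.parse_function()
            if word in ("model", "module"):
                return self.parse_model()
            if word == "at":
                return self.parse_event(label=None, start=tok)
            if word == "unit":
                return self.parse_unit()
            if word in ("const", "var", "species", "compartment", "formula"):
                return self.parse_var_decl()
            return self.parse_name_led()
        if tok.kind == "OP" and tok.text in ("$", "->", "=>"):
            return self.parse_reaction(label=None, start=tok)
        if tok.kind == "NUMBER":
            return self.parse_reaction(label=None, start=tok)
        raise _SyntaxError(tok.span, f"unexpected token '{tok.text}'", tok.kind in ("NEWLINE", "EOF"))

    def parse_name_led(self) -> AstNode:
        """Statement beginning with a bare identifier."""
        start = self.peek()
        nxt = self.peek(1)
        if nxt.kind == "OP" and nxt.text == ":":
            label_tok = self.advance()
            self.advance()  # ':'
            if self.at("NAME", "at"):
                return self.parse_event(label=label_tok, start=label_tok)
            # modular call: NAME '(' ... ')' with no reaction arrow ahead
            if self.at("NAME") and self.peek(1).kind == "OP" and self.peek(1).text == "(" \
                    and not self._arrow_ahead():
                return self.parse_modular_call(label_tok)
            return self.parse_reaction(label=label_tok, start=label_tok)
        if nxt.kind == "STRING" or (nxt.kind == "NAME" and nxt.text == "is"):
            if nxt.kind == "NAME" and nxt.text == "is":
                return self.parse_display_name()
        if nxt.kind == "NAME" and nxt.text in ANNOTATION_QUALIFIERS:
            return self.parse_annotation()
        if nxt.kind == "OP" and nxt.text in ("=", ":="):
            return self.parse_assignment()
        if nxt.kind == "OP" and nxt.text == "'":
            return self.parse_rate_rule()
        if nxt.kind == "NAME" and nxt.text == "in":
            return self.parse_var_decl()
        return self.parse_reaction(label=None, start=start)

    def _arrow_ahead(self) -> bool:
        i = self.pos
        while i < len(self.tokens):
            tok = self.tokens[i]
            if tok.kind in ("NEWLINE", "EOF"):
                return False
            if tok.kind == "OP" and tok.text in ("->", "=>"):
                return True
            if tok.kind == "OP" and tok.text == ";":
                return False
            i += 1
        return False

    def parse_import(self) -> AstNode:
        kw = self.expect("NAME", "import")
        path_tok = self.expect("STRING")
        self.end_statement()
        node = AstNode(
            "importStmt",
            kw.span.cover(path_tok.span),
            attrs={"path": path_tok.text[1:-1], "path_span": path_tok.span},
        )
        return node

    def parse_function(self) -> AstNode:
        kw = self.expect("NAME", "function")
        name_tok = self.expect("NAME")
        self.expect("OP", "(")
        params: list[str] = []
        param_spans: list[SourceSpan] = []
        if not self.at("OP", ")"):
            while True:
                p = self.expect("NAME")
                params.append(p.text)
                param_spans.append(p.span)
                if self.at("OP", ","):
                    self.advance()
                    continue
                break
        self.expect("OP", ")")
        self.skip_newlines()
        body = self.parse_math()
        self.skip_newlines()
        end_tok = self.expect("NAME", "end")
        self.end_statement()
        return AstNode(
            "functionDef",
            kw.span.cover(end_tok.span),
            children=[body],
            attrs={
                "name": name_tok.text,
                "name_span": name_tok.span,
                "params": tuple(params),
                "param_spans": tuple(param_spans),
            },
        )

    def parse_model(self) -> AstNode:
        kw = self.advance()  # model | module
        if self.at("OP", "*"):
            self.advance()  # "main model" marker, tolerated
        name_tok = self.expect("NAME")
        params: list[str] = []
        param_spans: list[SourceSpan] = []
        if self.at("OP", "("):
            self.advance()
            if not self.at("OP", ")"):
                while True:
                    p = self.expect("NAME")
                    params.append(p.text)
                    param_spans.append(p.span)
                    if self.at("OP", ","):
                        self.advance()
                        continue
                    break
            self.expect("OP", ")")
        children: list[AstNode] = []
        self.skip_newlines(children)
        while not self.at("NAME", "end"):
            if self.at("EOF"):
                raise _SyntaxError(self.peek().span, f"unexpected end of file inside model '{name_tok.text}'", True)
            try:
                stmt = self.parse_statement()
                if stmt is not None:
                    children.append(stmt)
            except _SyntaxError as exc:
                self.error(exc)
                self.recover()
            self.skip_newlines(children)
        end_tok = self.advance()
        self.end_statement()
        return AstNode(
            "modelDef",
            kw.span.cover(end_tok.span),
            children=children,
            attrs={
                "name": name_tok.text,
                "name_span": name_tok.span,
                "params": tuple(params),
                "param_spans": tuple(param_spans),
            },
        )

    def parse_event(self, label: Token | None, start: Token) -> AstNode:
        self.expect("NAME", "at")
        trigger = self.parse_math(stop_colon=True)
        assignments: list[AstNode] = []
        if self.at("OP", ":"):
            self.advance()
            while True:
                target = self.expect("NAME")
                self.expect("OP", "=")
                value = self.parse_math()
                assignments.append(
                    AstNode(
                        "eventAssignment",
                        target.span.cover(value.span),
                        children=[value],
                        attrs={"target": target.text, "target_span": target.span},
                    )
                )
                if self.at("OP", ","):
                    self.advance()
                    continue
                break
        self.end_statement()
        span = start.span
        for a in assignments:
            span = span.cover(a.span)
        span = span.cover(trigger.span)
        return AstNode(
            "eventStmt",
            span,
            children=[trigger] + assignments,
            attrs={
                "name": label.text if label else None,
                "name_span": label.span if label else None,
            },
        )

    def parse_unit(self) -> AstNode:
        kw = self.expect("NAME", "unit")
        name_tok = self.expect("NAME")
        self.expect("OP", "=")
        expr = self.parse_math()
        self.end_statement()
        return AstNode(
            "unitDecl",
            kw.span.cover(expr.span),
            children=[expr],
            attrs={"name": name_tok.text, "name_span": name_tok.span},
        )

    def parse_var_decl(self) -> AstNode:
        start = self.peek()
        const: bool | None = None
        type_kw: str | None = None
        if self.at("NAME", "const") or self.at("NAME", "var"):
            const = self.advance().text == "const"
        if self.peek().kind == "NAME" and self.peek().text in ("species", "compartment", "formula"):
            type_kw = self.advance().text
        entries: list[AstNode] = []
        last_span = start.span
        while True:
            fixed = False
            if self.at("OP", "$"):
                fixed = True
                self.advance()
            name_tok = self.expect("NAME")
            entry_span = name_tok.span
            compartment = None
            value = None
            if self.at("NAME", "in"):
                self.advance()
                comp_tok = self.expect("NAME")
                compartment = comp_tok.text
                entry_span = entry_span.cover(comp_tok.span)
            if self.at("OP", "="):
                self.advance()
                value = self.parse_math()
                entry_span = entry_span.cover(value.span)
            entries.append(
                AstNode(
                    "varEntry",
                    entry_span,
                    children=[value] if value is not None else [],
                    attrs={
                        "name": name_tok.text,
                        "name_span": name_tok.span,
                        "fixed": fixed,
                        "compartment": compartment,
                    },
                )
            )
            last_span = entry_span
            if self.at("OP", ","):
                self.advance()
                continue
            break
        self.end_statement()
        return AstNode(
            "varDecl",
            start.span.cover(last_span),
            children=entries,
            attrs={"const": const, "type": type_kw},
        )

    def parse_display_name(self) -> AstNode:
        name_tok = self.expect("NAME")
        self.expect("NAME", "is")
        str_tok = self.expect("STRING")
        self.end_statement()
        return AstNode(
            "displayNameStmt",
            name_tok.span.cover(str_tok.span),
            attrs={
                "name": name_tok.text,
                "name_span": name_tok.span,
                "display": str_tok.text[1:-1],
            },
        )

    def parse_annotation(self) -> AstNode:
        name_tok = self.expect("NAME")
        qual_tok = self.expect("NAME")
        uris: list[str] = []
        last = qual_tok
        while True:
            s = self.expect("STRING")
            uris.append(s.text[1:-1])
            last = s
            if self.at("OP", ","):
                self.advance()
                continue
            break
        self.end_statement()
        return AstNode(
            "annotationStmt",
            name_tok.span.cover(last.span),
            attrs={
                "name": name_tok.text,
                "name_span": name_tok.span,
                "qualifier": qual_tok.text,
                "uris": tuple(uris),
            },
        )

    def parse_assignment(self) -> AstNode:
        name_tok = self.expect("NAME")
        op = self.advance()  # '=' or ':='
        value = self.parse_math()
        self.end_statement()
        return AstNode(
            "assignmentStmt",
            name_tok.span.cover(value.span),
            children=[value],
            attrs={
                "name": name_tok.text,
                "name_span": name_tok.span,
                "rule": op.text == ":=",
            },
        )

    def parse_rate_rule(self) -> AstNode:
        name_tok = self.expect("NAME")
        self.expect("OP", "'")
        self.expect("OP", "=")
        value = self.parse_math()
        self.end_statement()
        return AstNode(
            "rateRuleStmt",
            name_tok.span.cover(value.span),
            children=[value],
            attrs={"name": name_tok.text, "name_span": name_tok.span},
        )

    def parse_modular_call(self, label: Token) -> AstNode:
        model_tok = self.expect("NAME")
        self.expect("OP", "(")
        args: list[AstNode] = []
        if not self.at("OP", ")"):
            while True:
                args.append(self.parse_math())
                if self.at("OP", ","):
                    self.advance()
                    continue
                break
        close = self.expect("OP", ")")
        self.end_statement()
        return AstNode(
            "modularCall",
            label.span.cover(close.span),
            children=args,
            attrs={
                "name": label.text,
                "name_span": label.span,
                "model": model_tok.text,
                "model_span": model_tok.span,
            },
        )

    # --- reactions ----------------------------------------------------------
    def parse_reaction(self, label: Token | None, start: Token) -> AstNode:
        reactants = self.parse_species_refs(role="reactant")
        arrow_tok = self.peek()
        if not (arrow_tok.kind == "OP" and arrow_tok.text in ("->", "=>")):
            raise _SyntaxError(
                arrow_tok.span,
                f"unexpected token '{arrow_tok.text or arrow_tok.kind.lower()}', expected a reaction arrow",
                arrow_tok.kind in ("NEWLINE", "EOF"),
            )
        self.advance()
        products = self.parse_species_refs(role="product")
        law: AstNode | None = None
        semi_tok: Token | None = None
        if self.at("OP", ";"):
            semi_tok = self.advance()
            nxt = self.peek()
            if nxt.kind in ("NEWLINE", "EOF"):
                raise _SyntaxError(
                    semi_tok.span, "unexpected newline after ';', expected a kinetic law", True
                )
            law = self.parse_math()
        self.end_statement()
        span = start.span.cover(arrow_tok.span)
        for n in reactants + products:
            span = span.cover(n.span)
        if law is not None:
            span = span.cover(law.span)
        children = reactants + products + ([law] if law is not None else [])
        return AstNode(
            "reactionStmt",
            span,
            children=children,
            attrs={
                "name": label.text if label else None,
                "name_span": label.span if label else None,
                "reversible": arrow_tok.text == "->",
                "arrow": arrow_tok.text,
                "arrow_span": arrow_tok.span,
                "n_reactants": len(reactants),
                "n_products": len(products),
            },
        )

    def parse_species_refs(self, role: str) -> list[AstNode]:
        refs: list[AstNode] = []
        tok = self.peek()
        if tok.kind == "OP" and tok.text in ("->", "=>", ";"):
            return refs  # empty side (synthesis/degradation)
        if tok.kind in ("NEWLINE", "EOF"):
            return refs
        while True:
            start = self.peek()
            stoich = 1.0
            if self.at("NUMBER"):
                stoich = float(self.advance().text)
            fixed = False
            if self.at("OP", "$"):
                fixed = True
                self.advance()
            name_tok = self.expect("NAME")
            refs.append(
                AstNode(
                    "speciesRef",
                    start.span.cover(name_tok.span),
                    text=name_tok.text,
                    attrs={
                        "stoichiometry": stoich,
                        "role": role,
                        "fixed": fixed,
                        "name_span": name_tok.span,
                    },
                )
            )
            if self.at("OP", "+"):
                self.advance()
                continue
            break
        return refs

    # --- math expressions -----------------------------------------------------
    def parse_math(self, stop_colon: bool = False) -> AstNode:
        expr = self.parse_or(stop_colon)
        return AstNode("mathExpr", expr.span, children=[expr])

    def parse_or(self, stop_colon: bool = False) -> AstNode:
        left = self.parse_and(stop_colon)
        while self.at("OP", "||"):
            self.advance()
            right = self.parse_and(stop_colon)
            left = AstNode("binaryOp", left.span.cover(right.span), [left, right], text="||")
        return left

    def parse_and(self, stop_colon: bool = False) -> AstNode:
        left = self.parse_not(stop_colon)
        while self.at("OP", "&&"):
            self.advance()
            right = self.parse_not(stop_colon)
            left = AstNode("binaryOp", left.span.cover(right.span), [left, right], text="&&")
        return left

    def parse_not(self, stop_colon: bool = False) -> AstNode:
        if self.at("OP", "!"):
            tok = self.advance()
            operand = self.parse_not(stop_colon)
            return AstNode("unaryOp", tok.span.cover(operand.span), [operand], text="!")
        return self.parse_comparison(stop_colon)

    def parse_comparison(self, stop_colon: bool = False) -> AstNode:
        left = self.parse_additive()
        tok = self.peek()
        if tok.kind == "OP" and tok.text in (">", "<", ">=", "<=", "==", "!="):
            self.advance()
            right = self.parse_additive()
            return AstNode("binaryOp", left.span.cover(right.span), [left, right], text=tok.text)
        return left

    def parse_additive(self) -> AstNode:
        left = self.parse_multiplicative()
        while True:
            tok = self.peek()
            if tok.kind == "OP" and tok.text in ("+", "-"):
                self.advance()
                right = self.parse_multiplicative()
                left = AstNode("binaryOp", left.span.cover(right.span), [left, right], text=tok.text)
            else:
                return left

    def parse_multiplicative(self) -> AstNode:
        left = self.parse_unary()
        while True:
            tok = self.peek()
            if tok.kind == "OP" and tok.text in ("*", "/"):
                self.advance()
                right = self.parse_unary()
                left = AstNode("binaryOp", left.span.cover(right.span), [left, right], text=tok.text)
            else:
                return left

    def parse_unary(self) -> AstNode:
        tok = self.peek()
        if tok.kind == "OP" and tok.text in ("+", "-"):
            self.advance()
            operand = self.parse_unary()
            return AstNode("unaryOp", tok.span.cover(operand.span), [operand], text=tok.text)
        return self.parse_power()

    def parse_power(self) -> AstNode:
        base = self.parse_postfix()
        if self.at("OP", "^"):
            self.advance()
            exponent = self.parse_unary()  # right-associative
            return AstNode("binaryOp", base.span.cover(exponent.span), [base, exponent], text="^")
        return base

    def parse_postfix(self) -> AstNode:
        tok = self.peek()
        if tok.kind == "NAME":
            nxt = self.peek(1)
            if nxt.kind == "OP" and nxt.text == "(":
                name_tok = self.advance()
                self.advance()  # '('
                args: list[AstNode] = []
                if not self.at("OP", ")"):
                    while True:
                        args.append(self.parse_math())
                        if self.at("OP", ","):
                            self.advance()
                            continue
                        break
                close = self.expect("OP", ")")
                return AstNode(
                    "call",
                    name_tok.span.cover(close.span),
                    children=args,
                    attrs={"name": name_tok.text, "name_span": name_tok.span},
                )
            self.advance()
            return AstNode("identifier", tok.span, text=tok.text)
        if tok.kind == "NUMBER":
            self.advance()
            return AstNode("number", tok.span, text=tok.text)
        if tok.kind == "OP" and tok.text == "(":
            self.advance()
            inner = self.parse_or()
            self.expect("OP", ")")
            return inner
        if tok.kind in ("NEWLINE", "EOF"):
            raise _SyntaxError(
                tok.span,
                f"unexpected {'newline' if tok.kind == 'NEWLINE' else 'end of file'} in expression",
                True,
            )
        raise _SyntaxError(tok.span, f"unexpected token '{tok.text}' in expression", False)
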