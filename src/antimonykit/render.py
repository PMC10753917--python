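"""Canonical pretty-printer for Antimony syntax trees.

``parse(render(ast))`` is structurally a fixed point: one statement per line,
single spaces around arrows and ``+``, minimal parentheses in expressions.
"""

from __future__ import annotations

from .ast import AstNode


class RenderError(ValueError):
    pass


_PRECEDENCE = {
    "||": 1,
    "&&": 2,
    "==": 3,
    "!=": 3,
    "<": 3,
    ">": 3,
    "<=": 3,
    ">=": 3,
    "+": 4,
    "-": 4,
    "*": 5,
    "/": 5,
    "^": 7,
}
_RIGHT_ASSOC = {"^"}


def render(ast: AstNode) -> str:
    if ast.kind != "document":
        raise RenderError(f"expected a document node, got '{ast.kind}'")
    lines = [_render_statement(child, indent=0) for child in ast.children]
    return "\n".join(lines) + ("\n" if lines else "")


def _render_statement(node: AstNode, indent: int) -> str:
    pad = "  " * indent
    k = node.kind
    if k == "comment":
        return pad + (node.text or "//")
    if k == "importStmt":
        return f'{pad}import "{node.get("path")}"'
    if k == "modelDef":
        params = node.get("params") or ()
        head = f'{pad}model {node.get("name")}'
        if params:
            head += "(" + ", ".join(params) + ")"
        body = [_render_statement(c, indent + 1) for c in node.children]
        return "\n".join([head] + body + [pad + "end"])
    if k == "functionDef":
        params = ", ".join(node.get("params") or ())
        body = render_math(node.children[0])
        return f'{pad}function {node.get("name")}({params})\n{pad}  {body}\n{pad}end'
    if k == "reactionStmt":
        return pad + _render_reaction(node)
    if k == "assignmentStmt":
        op = ":=" if node.get("rule") else "="
        return f'{pad}{node.get("name")} {op} {render_math(node.children[0])}'
    if k == "rateRuleStmt":
        return f'{pad}{node.get("name")}\' = {render_math(node.children[0])}'
    if k == "eventStmt":
        trigger = render_math(node.children[0])
        head = f'{node.get("name")}: ' if node.get("name") else ""
        assigns = [
            f'{a.get("target")} = {render_math(a.children[0])}'
            for a in node.children[1:]
        ]
        tail = ": " + ", ".join(assigns) if assigns else ""
        return f"{pad}{head}at {trigger}{tail}"
    if k == "varDecl":
        parts = []
        if node.get("const") is True:
            parts.append("const")
        elif node.get("const") is False:
            parts.append("var")
        if node.get("type"):
            parts.append(node.get("type"))
        entries = []
        for e in node.children:
            s = ("$" if e.get("fixed") else "") + e.get("name")
            if e.get("compartment"):
                s += f' in {e.get("compartment")}'
            if e.children:
                s += f" = {render_math(e.children[0])}"
            entries.append(s)
        return pad + " ".join(parts + [", ".join(entries)])
    if k == "displayNameStmt":
        return f'{pad}{node.get("name")} is "{node.get("display")}"'
    if k == "annotationStmt":
        uris = ", ".join(f'"{u}"' for u in node.get("uris"))
        return f'{pad}{node.get("name")} {node.get("qualifier")} {uris}'
    if k == "unitDecl":
        return f'{pad}unit {node.get("name")} = {render_math(node.children[0])}'
    if k == "modularCall":
        args = ", ".join(render_math(a) for a in node.children)
        return f'{pad}{node.get("name")}: {node.get("model")}({args})'
    raise RenderError(f"cannot render node of kind '{k}' as a statement")


def _render_reaction(node: AstNode) -> str:
    reactants = [c for c in node.children if c.kind == "speciesRef" and c.get("role") == "reactant"]
    products = [c for c in node.children if c.kind == "speciesRef" and c.get("role") == "product"]
    law = next((c for c in node.children if c.kind == "mathExpr"), None)
    arrow = "->" if node.get("reversible") else "=>"

    def side(refs: list[AstNode]) -> str:
        out = []
        for r in refs:
            stoich = r.get("stoichiometry", 1.0)
            prefix = "" if stoich == 1 else _fmt_number(stoich) + " "
            prefix += "$" if r.get("fixed") else ""
            out.append(prefix + (r.text or ""))
        return " + ".join(out)

    s = ""
    if node.get("name"):
        s += f'{node.get("name")}: '
    s += side(reactants)
    if reactants:
        s += " "
    s += arrow
    if products:
        s += " " + side(products)
    if law is not None:
        s += f"; {render_math(law)}"
    return s


def _fmt_number(x: float) -> str:
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def render_math(node: AstNode) -> str:
    if node.kind == "mathExpr":
        return render_math(node.children[0])
    if node.kind == "identifier":
        return node.text or ""
    if node.kind == "number":
        return node.text or "0"
    if node.kind == "call":
        args = ", ".join(render_math(a) for a in node.children)
        return f'{node.get("name")}({args})'
    if node.kind == "unaryOp":
        child = node.children[0]
        if child.kind == "mathExpr":
            child = child.children[0]
        operand = render_math(child)
        if child.kind == "binaryOp" and _PRECEDENCE.get(child.text or "", 0) < 6:
            operand = f"({operand})"
        return f"{node.text}{operand}"
    if node.kind == "binaryOp":
        op = node.text or "?"
        left = _child_str(node.children[0], op, "left")
        right = _child_str(node.children[1], op, "right")
        if op in ("*", "/", "^"):
            return f"{left}{op}{right}"
        return f"{left} {op} {right}"
    raise RenderError(f"cannot render node of kind '{node.kind}' in an expression")


def _child_str(child: AstNode, parent_op: str, side: str) -> str:
    if child.kind == "mathExpr":
        child = child.children[0]
    text = render_math(child)
    parent_prec = _PRECEDENCE.get(parent_op, 0)
    if child.kind == "binaryOp":
        child_prec = _PRECEDENCE.get(child.text or "", 0)
    elif child.kind == "unaryOp":
        child_prec = 6
    else:
        return text
    if child_prec < parent_prec:
        return f"({text})"
    if child_prec == parent_prec and child.kind == "binaryOp":
        if side == "left":
            if parent_op == "^":
                return f"({text})"  # ^ is right-associative
        else:
            if parent_op in ("+", "*") and child.text == parent_op:
                return text
            if parent_op == "^":
                return text
            return f"({text})"
    return text
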