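"""Bridge between Antimony expression trees and content MathML.

SBML kinetic laws, rules, triggers and function bodies store math as content
MathML; Antimony stores the same math as infix text.  Both directions are
implemented over the package's expression AST (``binaryOp``/``unaryOp``/
``call``/``identifier``/``number`` nodes).
"""

from __future__ import annotations

from lxml import etree

from .ast import AstNode, EMPTY_SPAN

MATHML_NS = "http://www.w3.org/1998/Math/MathML"
TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"


def _m(tag: str) -> str:
    return f"{{{MATHML_NS}}}{tag}"


_BINOP_TO_TAG = {
    "+": "plus",
    "-": "minus",
    "*": "times",
    "/": "divide",
    "^": "power",
    ">": "gt",
    "<": "lt",
    ">=": "geq",
    "<=": "leq",
    "==": "eq",
    "!=": "neq",
    "&&": "and",
    "||": "or",
}
_TAG_TO_BINOP = {v: k for k, v in _BINOP_TO_TAG.items()}

_FUNC_TO_TAG = {
    "abs": "abs",
    "acos": "arccos",
    "asin": "arcsin",
    "atan": "arctan",
    "ceil": "ceiling",
    "cos": "cos",
    "cosh": "cosh",
    "exp": "exp",
    "factorial": "factorial",
    "floor": "floor",
    "ln": "ln",
    "log": "log",
    "sin": "sin",
    "sinh": "sinh",
    "tan": "tan",
    "tanh": "tanh",
    "pow": "power",
    "root": "root",
}
_TAG_TO_FUNC = {v: k for k, v in _FUNC_TO_TAG.items() if v != "power"}


def expr_to_mathml(expr: AstNode) -> etree._Element:
    """Wrap an expression tree in a ``<math>`` element."""
    math = etree.Element(_m("math"), nsmap={None: MATHML_NS})
    math.append(_to_element(expr))
    return math


def _to_element(node: AstNode) -> etree._Element:
    if node.kind == "mathExpr":
        return _to_element(node.children[0])
    if node.kind == "number":
        cn = etree.Element(_m("cn"))
        text = node.text or "0"
        value = float(text)
        if value.is_integer() and "e" not in text.lower() and "." not in text:
            cn.set("type", "integer")
            cn.text = str(int(value))
        else:
            cn.text = repr(value)
        return cn
    if node.kind == "identifier":
        if node.text == "time":
            cs = etree.Element(_m("csymbol"))
            cs.set("encoding", "text")
            cs.set("definitionURL", TIME_CSYMBOL)
            cs.text = "time"
            return cs
        ci = etree.Element(_m("ci"))
        ci.text = node.text
        return ci
    if node.kind == "unaryOp":
        if node.text == "+":
            return _to_element(node.children[0])
        apply_ = etree.Element(_m("apply"))
        tag = "minus" if node.text == "-" else "not"
        apply_.append(etree.Element(_m(tag)))
        apply_.append(_to_element(node.children[0]))
        return apply_
    if node.kind == "binaryOp":
        apply_ = etree.Element(_m("apply"))
        apply_.append(etree.Element(_m(_BINOP_TO_TAG[node.text or "+"])))
        apply_.append(_to_element(node.children[0]))
        apply_.append(_to_element(node.children[1]))
        return apply_
    if node.kind == "call":
        name = node.get("name")
        apply_ = etree.Element(_m("apply"))
        if name == "sqrt":
            apply_.append(etree.Element(_m("root")))
            degree = etree.SubElement(apply_, _m("degree"))
            cn = etree.SubElement(degree, _m("cn"))
            cn.set("type", "integer")
            cn.text = "2"
        elif name in _FUNC_TO_TAG:
            apply_.append(etree.Element(_m(_FUNC_TO_TAG[name])))
        else:
            ci = etree.Element(_m("ci"))
            ci.text = name
            apply_.append(ci)
        for arg in node.children:
            apply_.append(_to_element(arg))
        return apply_
    raise ValueError(f"cannot serialize node kind '{node.kind}' to MathML")


def mathml_to_expr(element: etree._Element) -> AstNode:
    """Convert a ``<math>`` element (or its child) to an expression tree."""
    if _local(element.tag) == "math":
        children = _element_children(element)
        if not children:
            raise ValueError("empty <math> element")
        return AstNode("mathExpr", EMPTY_SPAN, [_from_element(children[0])])
    return AstNode("mathExpr", EMPTY_SPAN, [_from_element(element)])


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) else ""


def _element_children(el: etree._Element) -> list:
    return [c for c in el if isinstance(c.tag, str)]


def _num_node(text: str) -> AstNode:
    return AstNode("number", EMPTY_SPAN, text=text)


def _from_element(el: etree._Element) -> AstNode:
    tag = _local(el.tag)
    if tag == "cn":
        cn_type = el.get("type", "real")
        if cn_type == "e-notation":
            kids = [t.strip() for t in el.itertext()]
            parts = [t for t in kids if t]
            mantissa = parts[0] if parts else "0"
            exponent = parts[1] if len(parts) > 1 else "0"
            return _num_node(f"{mantissa}e{exponent}")
        if cn_type == "rational":
            parts = [t for t in (t.strip() for t in el.itertext()) if t]
            num = float(parts[0]) / float(parts[1] if len(parts) > 1 else 1)
            return _num_node(repr(num))
        text = (el.text or "0").strip()
        return _num_node(text)
    if tag == "ci":
        return AstNode("identifier", EMPTY_SPAN, text=(el.text or "").strip())
    if tag == "csymbol":
        return AstNode("identifier", EMPTY_SPAN, text=(el.text or "time").strip())
    if tag in ("true", "false", "pi", "exponentiale", "infinity", "notanumber"):
        return AstNode("identifier", EMPTY_SPAN, text=tag)
    if tag == "piecewise":
        args: list[AstNode] = []
        for piece in _element_children(el):
            args.extend(_from_element(c) for c in _element_children(piece))
        return AstNode("call", EMPTY_SPAN, children=args, attrs={"name": "piecewise"})
    if tag != "apply":
        raise ValueError(f"unsupported MathML element <{tag}>")

    children = _element_children(el)
    head = children[0]
    head_tag = _local(head.tag)
    args = [
        _from_element(c)
        for c in children[1:]
        if _local(c.tag) not in ("degree", "logbase")
    ]

    if head_tag == "ci":  # user-defined function call
        return AstNode(
            "call", EMPTY_SPAN, children=args, attrs={"name": (head.text or "").strip()}
        )
    if head_tag == "minus" and len(args) == 1:
        return AstNode("unaryOp", EMPTY_SPAN, args, text="-")
    if head_tag == "not":
        return AstNode("unaryOp", EMPTY_SPAN, args, text="!")
    if head_tag == "root":
        degrees = [c for c in children[1:] if _local(c.tag) == "degree"]
        if not degrees or _degree_is_two(degrees[0]):
            return AstNode("call", EMPTY_SPAN, children=args, attrs={"name": "sqrt"})
        deg = _from_element(_element_children(degrees[0])[0])
        inv = AstNode("binaryOp", EMPTY_SPAN, [_num_node("1"), deg], text="/")
        return AstNode("binaryOp", EMPTY_SPAN, [args[0], inv], text="^")
    if head_tag == "power":
        return AstNode("binaryOp", EMPTY_SPAN, args, text="^")
    if head_tag == "log":
        logbase = [c for c in children[1:] if _local(c.tag) == "logbase"]
        if logbase:
            base = _from_element(_element_children(logbase[0])[0])
            if base.kind == "number" and float(base.text) == 10.0:
                return AstNode("call", EMPTY_SPAN, children=args, attrs={"name": "log10"})
        return AstNode("call", EMPTY_SPAN, children=args, attrs={"name": "log"})
    if head_tag in _TAG_TO_BINOP:
        op = _TAG_TO_BINOP[head_tag]
        if len(args) == 1:
            return args[0]
        node = args[0]
        for arg in args[1:]:
            node = AstNode("binaryOp", EMPTY_SPAN, [node, arg], text=op)
        return node
    if head_tag in _TAG_TO_FUNC:
        return AstNode("call", EMPTY_SPAN, children=args, attrs={"name": _TAG_TO_FUNC[head_tag]})
    raise ValueError(f"unsupported MathML operator <{head_tag}>")


def _degree_is_two(degree_el: etree._Element) -> bool:
    kids = _element_children(degree_el)
    if not kids:
        return True
    node = _from_element(kids[0])
    return node.kind == "number" and float(node.text) == 2.0
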