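"""Kinetic rate-law templates and their instantiation for a reaction.

The registry ships the standard families: irreversible and reversible mass
action, irreversible and (simplified) reversible Michaelis–Menten, and a
Hill expression.  Instantiating a template fills reactant/product slots from
the reaction (stoichiometry n > 1 becomes a power ``S^n``) and renders every
constant the user still has to supply as a literal ``__`` placeholder; a
document containing ``__`` tokens is a draft, flagged by
:func:`pending_placeholders` as a warning, not an error.

When every species participating in the reaction sits in the same declared
compartment, the instantiated law is prefixed with that compartment as a
volume factor (e.g. ``cell*k*S``); otherwise no factor is added.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Optional

from .ast import AstNode, SourceSpan
from .parser import parse
from .render import render
from .symbols import MAIN_SCOPE, ReactionInfo, SymbolTable, build_symbol_table

PLACEHOLDER = "__"

_SLOT_RE = re.compile(r"\{([A-Za-z][A-Za-z0-9]*)\}")

_ARITY_NAMES = {0: "Nil", 1: "Uni", 2: "Bi", 3: "Ter", 4: "Quad"}


class RateLawError(ValueError):
    pass


@dataclass(frozen=True)
class RateLawTemplate:
    id: str
    display_base: str
    reversibility: str  # "irreversible" | "reversible" | "any"
    min_reactants: int = 0
    max_reactants: Optional[int] = None
    min_products: int = 0
    max_products: Optional[int] = None
    arity_suffix: bool = False
    # pattern builder: (reactant_terms, product_terms) -> slot pattern, where
    # slots are written {role} and species terms are already exponentiated
    build: Callable[[list[str], list[str]], str] = None  # type: ignore[assignment]

    def matches(self, reaction: ReactionInfo | AstNode) -> bool:
        info = _as_info(reaction)
        n_r, n_p = len(info.reactants), len(info.products)
        if self.max_reactants is not None and n_r > self.max_reactants:
            return False
        if self.max_products is not None and n_p > self.max_products:
            return False
        if n_r < self.min_reactants or n_p < self.min_products:
            return False
        if self.reversibility == "any":
            return True
        wanted = "reversible" if info.reversible else "irreversible"
        return self.reversibility == wanted

    def display_name_for(self, reaction: ReactionInfo | AstNode) -> str:
        if not self.arity_suffix:
            return self.display_base
        info = _as_info(reaction)
        r = _ARITY_NAMES.get(len(info.reactants), f"{len(info.reactants)}")
        p = _ARITY_NAMES.get(len(info.products), f"{len(info.products)}")
        return f"{self.display_base} {r}-{p}"


@dataclass
class InstantiatedRateLaw:
    expression_text: str  # with "__" placeholder tokens
    placeholders: list[tuple[str, str]]  # (token, role), first-occurrence order
    _pattern: str = field(repr=False, default="")

    def bind(self, bindings: dict[str, str]) -> str:
        """Substitute placeholder roles with identifiers; unbound roles stay ``__``."""
        def repl(m: re.Match) -> str:
            return bindings.get(m.group(1), PLACEHOLDER)

        return _SLOT_RE.sub(repl, self._pattern)


def _species_terms(side: list[tuple[str, float, bool]]) -> list[str]:
    terms = []
    for name, stoich, _fixed in side:
        if stoich == 1:
            terms.append(name)
        else:
            n = int(stoich) if float(stoich).is_integer() else stoich
            terms.append(f"{name}^{n}")
    return terms


def _mass_action_irrev(r: list[str], _p: list[str]) -> str:
    return "*".join(["{k}"] + r)


def _mass_action_rev(r: list[str], p: list[str]) -> str:
    return "*".join(["{kf}"] + r) + " - " + "*".join(["{kr}"] + p)


def _mm_irrev(r: list[str], _p: list[str]) -> str:
    s = r[0]
    return f"{{Vmax}}*{s}/({{Km}} + {s})"


def _mm_rev(r: list[str], p: list[str]) -> str:
    s, q = r[0], p[0]
    return f"({{Vf}}*{s} - {{Vr}}*{q})/({{Km}} + {s} + {q})"


def _hill(r: list[str], _p: list[str]) -> str:
    s = r[0]
    return f"{{Vmax}}*{s}^{{h}}/({{K}}^{{h}} + {s}^{{h}})"


REGISTRY: list[RateLawTemplate] = [
    RateLawTemplate(
        "mass_action_irrev", "Irreversible Mass-Action", "irreversible",
        min_reactants=1, arity_suffix=True, build=_mass_action_irrev,
    ),
    RateLawTemplate(
        "mass_action_rev", "Reversible Mass-Action", "reversible",
        min_reactants=1, min_products=1, arity_suffix=True, build=_mass_action_rev,
    ),
    RateLawTemplate(
        "michaelis_menten_irrev", "Irreversible Michaelis-Menten", "irreversible",
        min_reactants=1, max_reactants=1, build=_mm_irrev,
    ),
    RateLawTemplate(
        "michaelis_menten_rev", "Reversible Michaelis-Menten", "reversible",
        min_reactants=1, max_reactants=1, min_products=1, max_products=1,
        build=_mm_rev,
    ),
    RateLawTemplate(
        "hill", "Hill", "any", min_reactants=1, max_reactants=1, build=_hill,
    ),
]

_REGISTRY_INDEX = {t.id: t for t in REGISTRY}


def get_template(template_id: str) -> RateLawTemplate:
    try:
        return _REGISTRY_INDEX[template_id]
    except KeyError:
        raise RateLawError(f"unknown rate-law template '{template_id}'") from None


def applicable_templates(reaction: ReactionInfo | AstNode) -> list[RateLawTemplate]:
    """Templates whose arity/reversibility constraint matches, registry order."""
    return [t for t in REGISTRY if t.matches(reaction)]


_ROLE_NAMES = {
    "k": "rateConstant",
    "kf": "forwardRateConstant",
    "kr": "reverseRateConstant",
    "Vmax": "Vmax",
    "Vf": "forwardVmax",
    "Vr": "reverseVmax",
    "Km": "Km",
    "K": "halfSaturation",
    "h": "hillCoefficient",
}


def instantiate_rate_law(
    template: RateLawTemplate,
    reaction: ReactionInfo | AstNode,
    table: Optional[SymbolTable] = None,
) -> InstantiatedRateLaw:
    """Fill a template's species slots from the reaction.

    Constants become ``__`` placeholders; the shared compartment of the
    participating species, when one is declared (``table`` provided), is
    prepended as a volume factor.
    """
    info = _as_info(reaction)
    if not template.matches(info):
        raise RateLawError(
            f"template '{template.id}' does not apply: reaction has "
            f"{len(info.reactants)} reactant(s), {len(info.products)} product(s), "
            f"{'reversible' if info.reversible else 'irreversible'} arrow"
        )
    pattern = template.build(
        _species_terms(info.reactants), _species_terms(info.products)
    )
    comp = _shared_compartment(info, table)
    if comp:
        pattern = f"{comp}*{pattern}"
    roles: list[str] = []
    for m in _SLOT_RE.finditer(pattern):
        if m.group(1) not in roles:
            roles.append(m.group(1))
    text = _SLOT_RE.sub(PLACEHOLDER, pattern)
    placeholders = [(PLACEHOLDER, _ROLE_NAMES.get(r, r)) for r in roles]
    law = InstantiatedRateLaw(text, placeholders, _pattern=pattern)
    return law


def _shared_compartment(info: ReactionInfo, table: Optional[SymbolTable]) -> Optional[str]:
    if table is None:
        return None
    names = [n for n, _s, _f in info.reactants + info.products]
    if not names:
        return None
    comps = set()
    for name in names:
        sym = table.lookup(name)
        comps.add(sym.compartment_of if sym else None)
    if len(comps) == 1:
        return comps.pop()
    return None


def _as_info(reaction: ReactionInfo | AstNode) -> ReactionInfo:
    if isinstance(reaction, ReactionInfo):
        return reaction
    if isinstance(reaction, AstNode) and reaction.kind == "reactionStmt":
        doc = AstNode("document", reaction.span, [reaction])
        table = build_symbol_table(doc)
        return table.scopes[MAIN_SCOPE].reactions[0]
    raise RateLawError("expected a reaction statement")


def insert_rate_law(
    document: str,
    reaction_name: str,
    template_id: str,
    bindings: Optional[dict[str, str]] = None,
) -> str:
    """Insert (or replace) the kinetic law of a named reaction in a document.

    Unbound constants remain as ``__`` tokens; use
    :func:`pending_placeholders` to list drafts still awaiting user text.
    Role keys for ``bindings`` are the short slot names (k, kf, kr, Vmax,
    Vf, Vr, Km, K, h).
    """
    result = parse(document)
    table = build_symbol_table(result.ast)
    target: Optional[ReactionInfo] = None
    for scope in table.scopes.values():
        for rx in scope.reactions:
            if rx.name == reaction_name:
                target = rx
                break
    if target is None:
        raise RateLawError(f"no reaction named '{reaction_name}' in document")
    template = get_template(template_id)
    law = instantiate_rate_law(template, target, table)
    law_text = law.bind(bindings or {})

    # splice: rewrite the reaction's line, preserving everything else
    lines = document.split("\n")
    span = target.node.span
    original = span.slice(document)
    if ";" in original:
        new_stmt = original[: original.index(";")] + "; " + law_text
    else:
        new_stmt = original + "; " + law_text
    prefix = lines[span.line_start][: span.col_start]
    suffix = lines[span.line_end][span.col_end :]
    replacement = (prefix + new_stmt + suffix).split("\n")
    lines[span.line_start : span.line_end + 1] = replacement
    return "\n".join(lines)


def pending_placeholders(document: str) -> list[SourceSpan]:
    """Spans of ``__`` placeholder tokens still awaiting user-supplied text."""
    from .lexer import tokenize

    return [
        tok.span
        for tok in tokenize(document)
        if tok.kind == "NAME" and tok.text == PLACEHOLDER
    ]
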