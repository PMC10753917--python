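"""Rate-law template applicability, instantiation and insertion."""

import pytest

from antimonykit import build_symbol_table, parse
from antimonykit.ratelaws import (
    RateLawError,
    applicable_templates,
    get_template,
    insert_rate_law,
    instantiate_rate_law,
    pending_placeholders,
)


def _reaction(text: str):
    return parse(text).ast.children[0]


class TestApplicability:
    def test_bi_uni_irreversible_includes_mass_action(self):
        rx = _reaction("BLL + DL => ILL")
        templates = applicable_templates(rx)
        ids = [t.id for t in templates]
        assert "mass_action_irrev" in ids
        ma = get_template("mass_action_irrev")
        assert ma.display_name_for(rx) == "Irreversible Mass-Action Bi-Uni"

    def test_uni_irreversible_offers_mass_action_and_michaelis_menten(self):
        rx = _reaction("S => P")
        ids = [t.id for t in applicable_templates(rx)]
        assert "mass_action_irrev" in ids
        assert "michaelis_menten_irrev" in ids
        assert "hill" in ids

    def test_zero_reactants_excludes_mass_action(self):
        rx = _reaction("=> P")
        ids = [t.id for t in applicable_templates(rx)]
        assert "mass_action_irrev" not in ids

    def test_reversible_arrow_selects_reversible_family(self):
        rx = _reaction("S -> P")
        ids = [t.id for t in applicable_templates(rx)]
        assert "mass_action_rev" in ids
        assert "mass_action_irrev" not in ids
        assert "hill" in ids  # wildcard reversibility

    def test_registry_order_is_stable(self):
        rx = _reaction("S => P")
        assert [t.id for t in applicable_templates(rx)] == [
            t.id for t in applicable_templates(rx)
        ]


class TestInstantiation:
    def test_phosphotransfer_worked_example(self):
        rx = _reaction("Yp+TTWWAAp=>Ypp+TTWWAA")
        law = instantiate_rate_law(get_template("mass_action_irrev"), rx)
        assert law.expression_text.replace(" ", "") == "__*Yp*TTWWAAp"
        assert law.placeholders == [("__", "rateConstant")]
        bound = law.bind({"k": "phosphotransfer_r12_k1"})
        assert bound.replace(" ", "") == "phosphotransfer_r12_k1*Yp*TTWWAAp"

    def test_bi_uni_mass_action(self):
        rx = _reaction("BLL + DL => ILL")
        law = instantiate_rate_law(get_template("mass_action_irrev"), rx)
        assert law.expression_text == "__*BLL*DL"

    def test_stoichiometry_becomes_power(self):
        rx = _reaction("2 H2 + O2 => 2 H2O")
        law = instantiate_rate_law(get_template("mass_action_irrev"), rx)
        assert law.expression_text == "__*H2^2*O2"

    def test_compartment_factor_when_species_share_one(self):
        doc = (
            "compartment cell\ncell = 1\n"
            "species Yp in cell, TTWWAAp in cell, Ypp in cell, TTWWAA in cell\n"
            "Yp = 1\nTTWWAAp = 1\nYpp = 0\nTTWWAA = 0\n"
            "J12: Yp + TTWWAAp => Ypp + TTWWAA\n"
        )
        result = parse(doc)
        table = build_symbol_table(result.ast)
        rx = table.scopes["__main"].reactions[0]
        law = instantiate_rate_law(get_template("mass_action_irrev"), rx, table)
        assert law.expression_text == "cell*__*Yp*TTWWAAp"

    def test_inapplicable_template_raises(self):
        rx = _reaction("A + B => C")
        with pytest.raises(RateLawError, match="does not apply"):
            instantiate_rate_law(get_template("michaelis_menten_irrev"), rx)

    def test_substitution_closure(self):
        """Binding every placeholder to a fresh identifier yields a reaction
        statement that parses with zero syntax errors."""
        cases = [
            ("S => P", "mass_action_irrev"),
            ("S -> P", "mass_action_rev"),
            ("S => P", "michaelis_menten_irrev"),
            ("S -> P", "michaelis_menten_rev"),
            ("S => P", "hill"),
            ("A + 2 B => C", "mass_action_irrev"),
        ]
        for text, template_id in cases:
            rx = _reaction(text)
            law = instantiate_rate_law(get_template(template_id), rx)
            bindings = {}
            for i, (_tok, role) in enumerate(law.placeholders):
                short = _short_role(role)
                bindings[short] = f"p{i}"
            bound = law.bind(bindings)
            assert "__" not in bound
            stmt = f"{text}; {bound}"
            assert parse(stmt).errors == [], stmt

    def test_mass_action_references_exactly_the_reactant_set(self):
        rx = _reaction("2 H2 + O2 => 2 H2O")
        law = instantiate_rate_law(get_template("mass_action_irrev"), rx)
        factors = law.expression_text.split("*")[1:]
        assert sorted(factors) == ["H2^2", "O2"]


def _short_role(role: str) -> str:
    return {
        "rateConstant": "k",
        "forwardRateConstant": "kf",
        "reverseRateConstant": "kr",
        "forwardVmax": "Vf",
        "reverseVmax": "Vr",
        "halfSaturation": "K",
        "hillCoefficient": "h",
    }.get(role, role)


class TestInsertion:
    DOC = (
        "Yp = 1\nTTWWAAp = 1\nYpp = 0\nTTWWAA = 0\n"
        "J12: Yp + TTWWAAp => Ypp + TTWWAA\n"
    )

    def test_bound_insertion(self):
        new = insert_rate_law(
            self.DOC, "J12", "mass_action_irrev", {"k": "phosphotransfer_r12_k1"}
        )
        line = next(l for l in new.split("\n") if l.startswith("J12"))
        assert line.endswith("; phosphotransfer_r12_k1*Yp*TTWWAAp")
        # a parameter placeholder remains unfilled semantically, but the
        # document still parses
        assert parse(new).errors == []

    def test_unbound_insertion_leaves_draft_placeholder(self):
        new = insert_rate_law(self.DOC, "J12", "mass_action_irrev")
        line = next(l for l in new.split("\n") if l.startswith("J12"))
        assert "__" in line
        assert len(pending_placeholders(new)) == 1

    def test_insertion_replaces_existing_law(self):
        doc = self.DOC.replace(
            "J12: Yp + TTWWAAp => Ypp + TTWWAA",
            "J12: Yp + TTWWAAp => Ypp + TTWWAA; 1",
        )
        new = insert_rate_law(doc, "J12", "mass_action_irrev", {"k": "kx"})
        line = next(l for l in new.split("\n") if l.startswith("J12"))
        assert line.endswith("; kx*Yp*TTWWAAp")
        assert "; 1" not in line

    def test_unknown_reaction_raises(self):
        with pytest.raises(RateLawError, match="no reaction named"):
            insert_rate_law(self.DOC, "Jmissing", "mass_action_irrev")

    def test_unknown_template_raises(self):
        with pytest.raises(RateLawError, match="unknown rate-law template"):
            insert_rate_law(self.DOC, "J12", "not_a_template")

    def test_other_lines_untouched(self):
        new = insert_rate_law(self.DOC, "J12", "mass_action_irrev")
        assert new.split("\n")[:4] == self.DOC.split("\n")[:4]
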