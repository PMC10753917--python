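"""Parser, renderer and span behavior."""

import pytest
from hypothesis import given, settings, strategies as st

from antimonykit import node_at, parse, render, structurally_equal
from antimonykit.ast import AstNode

from conftest import CORPUS


class TestParse:
    def test_reaction_structure(self):
        result = parse("O2 + 2 H2 -> 2 H2O")
        assert not result.errors
        (rx,) = result.ast.children
        assert rx.kind == "reactionStmt"
        assert rx.get("reversible") is True
        refs = [
            (c.text, c.get("stoichiometry"), c.get("role"))
            for c in rx.children
            if c.kind == "speciesRef"
        ]
        assert refs == [
            ("O2", 1.0, "reactant"),
            ("H2", 2.0, "reactant"),
            ("H2O", 2.0, "product"),
        ]
        assert not any(c.kind == "mathExpr" for c in rx.children)

    def test_empty_input(self):
        result = parse("")
        assert result.ast.kind == "document"
        assert result.ast.children == []
        assert result.errors == []

    def test_irreversible_arrow_with_four_factor_law(self):
        result = parse(
            "Yp + TTWWAAp => Ypp + TTWWAA; cell*phosphotransfer_r12_k1*Yp*TTWWAAp"
        )
        assert not result.errors
        (rx,) = result.ast.children
        assert rx.get("reversible") is False
        law = next(c for c in rx.children if c.kind == "mathExpr")
        idents = [n.text for n in law.walk() if n.kind == "identifier"]
        assert idents == ["cell", "phosphotransfer_r12_k1", "Yp", "TTWWAAp"]

    def test_missing_kinetic_law_after_semicolon(self):
        result = parse("A => ;")
        assert len(result.errors) == 1
        err = result.errors[0]
        assert err.rule_id == "GEN004"
        assert (err.span.line_start, err.span.col_start) == (0, 5)  # the ';'

    def test_error_recovery_keeps_surrounding_statements(self):
        result = parse("A = 1\nB => ;\nC = 3\n")
        kinds = [c.kind for c in result.ast.children]
        assert kinds == ["assignmentStmt", "assignmentStmt"]
        assert len(result.errors) == 1

    def test_comments_preserved_as_nodes(self):
        result = parse("// head\nA = 1 /* tail */\n")
        comments = [n.text for n in result.ast.find_all("comment")]
        assert comments == ["// head", "/* tail */"]

    @pytest.mark.parametrize("name", sorted(CORPUS))
    def test_corpus_parses_cleanly(self, name):
        assert parse(CORPUS[name]).errors == []


class TestRender:
    def test_combustion_round_trip_text(self):
        ast = parse("O2 + 2 H2 -> 2 H2O").ast
        assert render(ast) == "O2 + 2 H2 -> 2 H2O\n"

    def test_empty_document(self):
        assert render(parse("").ast) == ""

    def test_parse_render_parse_fixed_point(self, corpus_model):
        first = parse(corpus_model).ast
        second = parse(render(first)).ast
        assert structurally_equal(first, second)

    def test_generated_corpus_fixed_point(self, generated_corpus):
        for text in generated_corpus:
            first = parse(text).ast
            assert structurally_equal(first, parse(render(first)).ast)

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["Glu", "ATP", "pyr_1", "NADH", "x"]),
                st.integers(1, 4),
            ),
            min_size=1,
            max_size=3,
            unique_by=lambda t: t[0],
        ),
        st.sampled_from(["->", "=>"]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reaction_render_fixed_point(self, refs, arrow):
        lhs = " + ".join(f"{s} {n}" if s > 1 else n for n, s in refs)
        text = f"{lhs} {arrow} {refs[0][0]}"
        first = parse(text).ast
        assert parse(text).errors == []
        assert structurally_equal(first, parse(render(first)).ast)


class TestSpans:
    def test_span_soundness(self, corpus_model):
        """Slicing the source by any node's span reproduces its lexical extent."""
        ast = parse(corpus_model).ast
        for node in ast.walk():
            if node.kind in ("identifier", "speciesRef", "number", "comment"):
                sliced = node.span.slice(corpus_model)
                if node.kind == "speciesRef":
                    assert sliced.endswith(node.text)
                elif node.text is not None:
                    assert sliced == node.text

    def test_node_at_matches_brute_force(self, corpus_model):
        ast = parse(corpus_model).ast
        lines = corpus_model.split("\n")
        for line_no, line in enumerate(lines):
            for col in range(len(line)):
                got = node_at(ast, (line_no, col))
                expected = _brute_force_deepest(ast, line_no, col)
                assert got is expected

    def test_node_at_arrow_returns_reaction(self):
        ast = parse("J0: A -> B; k*A").ast
        node = node_at(ast, (0, 6))  # on the '->'
        assert node.kind == "reactionStmt"

    def test_node_at_species_leaf(self):
        ast = parse("React1: BLL + DL => ILL").ast
        node = node_at(ast, (0, 9))
        assert node.kind == "speciesRef"
        assert node.text == "BLL"

    def test_node_at_past_eof(self):
        assert node_at(parse("A = 1").ast, (10, 0)) is None

    def test_sibling_spans_do_not_overlap(self, corpus_model):
        ast = parse(corpus_model).ast
        for node in ast.walk():
            spans = [c.span for c in node.children]
            for i, a in enumerate(spans):
                for b in spans[i + 1 :]:
                    assert a.end() <= b.start() or b.end() <= a.start()


def _brute_force_deepest(ast: AstNode, line: int, col: int):
    best, best_depth = None, -1

    def visit(node, depth):
        nonlocal best, best_depth
        if node.span.contains(line, col) and depth > best_depth:
            best, best_depth = node, depth
        for c in node.children:
            visit(c, depth + 1)

    visit(ast, 0)
    return best
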