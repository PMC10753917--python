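"""Hover, completion, navigation, token classification and coverage."""

from antimonykit.editor import (
    annotation_coverage,
    classify_tokens,
    complete,
    completion_context,
    goto_definition,
    hover,
)
from antimonykit.annotations import AnnotationHit, apply_annotation
from antimonykit.fixtures import synthetic_chemotaxis_model
from antimonykit.lexer import tokenize

GLU_MODEL = (
    "glucose_rate = 3\n"
    "glucose_k1 = 0.1\n"
    "species A, B\n"
    "A = 1\n"
    "B = 2\n"
)

ANNOTATED = (
    "compartment cell\n"
    "cell = 1\n"
    "species BLL in cell\n"
    "BLL = 2\n"
    "k1 = 0.5\n"
    "J0: BLL => ; k1*BLL\n"
    'BLL identity "https://identifiers.org/chebi/CHEBI:28262"\n'
)


class TestHover:
    def test_species_hover_shows_type_value_annotation(self):
        content = hover(ANNOTATED, (5, 5))  # on BLL inside the reaction
        assert content.symbol_name == "BLL"
        assert content.type_tag == "species"
        assert content.value_text == "2"
        assert content.compartment == "cell"
        assert content.annotations == ["https://identifiers.org/chebi/CHEBI:28262"]
        assert "type: species" in content.text()

    def test_whitespace_hover_is_none(self):
        assert hover("A = 1\n\nB = 2\n", (1, 0)) is None

    def test_function_hover_has_signature(self):
        doc = "function MM(S, Vm, Km)\n  Vm*S/(Km + S)\nend\nx = MM(1, 2, 3)\n"
        content = hover(doc, (3, 5))
        assert content.type_tag == "function"
        assert content.signature == ["S", "Vm", "Km"]

    def test_import_hover_previews_symbols(self):
        files = {"lib.ant": "lib_k = 1\nspecies L\nL = 2\n"}
        content = hover('import "lib.ant"\n', (0, 3), loader=files.__getitem__)
        assert content.type_tag == "import"
        assert "lib_k: parameter" in content.preview
        assert "L: species" in content.preview


class TestCompletion:
    def test_rate_law_context_suggests_both_glucose_parameters(self):
        doc = GLU_MODEL + "J0: A => B; glu"
        items = complete(doc, (5, len("J0: A => B; glu")))
        assert [i.label for i in items] == ["glucose_k1", "glucose_rate"]

    def test_reactant_context_excludes_parameters(self):
        doc = GLU_MODEL + "A + glu"
        items = complete(doc, (5, len("A + glu")))
        assert items == []

    def test_chemotaxis_reactant_prefix(self):
        doc = synthetic_chemotaxis_model() + "Yp+TTWW"
        line = len(doc.split("\n")) - 1
        items = complete(doc, (line, len("Yp+TTWW")))
        assert [i.label for i in items] == ["TTWWAA", "TTWWAAp"]

    def test_empty_prefix_general_context_lists_everything(self):
        items = complete(GLU_MODEL, (4, 0))
        labels = {i.label for i in items}
        assert {"glucose_rate", "glucose_k1", "A", "B"} <= labels

    def test_reactant_candidates_subset_of_general(self):
        doc = GLU_MODEL + "A + "
        reactant = {i.label for i in complete(doc, (5, 4))}
        general = {i.label for i in complete(GLU_MODEL, (4, 0))}
        assert reactant <= general

    def test_candidates_prefix_match_and_resolve(self):
        from antimonykit import build_symbol_table, parse

        doc = GLU_MODEL + "J0: A => B; g"
        table = build_symbol_table(parse(doc).ast)
        for item in complete(doc, (5, len("J0: A => B; g"))):
            assert item.label.startswith("g")
            assert table.lookup(item.label) is not None

    def test_context_detection(self):
        assert completion_context("A + B", (0, 5))[0] == "reactant"
        assert completion_context("A + B => C", (0, 10))[0] == "product"
        assert completion_context("A => B; k", (0, 9))[0] == "kineticLaw"
        assert completion_context("x = ", (0, 4))[0] == "assignmentRhs"
        assert completion_context("glu", (0, 3)) == ("general", "glu")


class TestNavigation:
    DOC = "k1 = 0.5\nS = 1\nJ0: S => ; k1*S\n"

    def test_rate_law_use_jumps_to_assignment(self):
        spans = goto_definition(self.DOC, (2, 11))  # k1 inside law
        assert spans
        assert spans[0].line_start == 0

    def test_declaration_is_fixed_point(self):
        spans = goto_definition(self.DOC, (0, 0))
        assert spans[0].line_start == 0

    def test_reaction_participant_points_at_first_occurrence(self):
        doc = "J0: Q => ; 1\nQ = 1\n"
        spans = goto_definition(doc, (0, 4))
        assert spans[0].line_start == 0
        assert spans[0].col_start == 4
        # initialization is a distinct second target
        assert len(spans) == 2
        assert spans[1].line_start == 1

    def test_off_symbol_is_empty(self):
        assert goto_definition(self.DOC, (0, 3)) == []


class TestClassification:
    def test_reaction_line_classes(self):
        doc = "J0: A -> B; k*A"
        classes = {doc[s.col_start : s.col_end]: cls for s, cls in classify_tokens(doc)}
        assert classes["J0"] == "reactionName"
        assert classes["A"] == "speciesName"
        assert classes["B"] == "speciesName"
        assert classes["k"] == "parameterName"
        assert classes["->"] == "operator"
        assert classes[";"] == "operator"

    def test_comment_single_span(self):
        out = classify_tokens("// hi")
        assert out == [(out[0][0], "comment")]

    def test_spans_cover_all_tokens_without_overlap(self, corpus_model):
        out = classify_tokens(corpus_model)
        toks = [
            t for t in tokenize(corpus_model) if t.kind not in ("NEWLINE", "EOF")
        ]
        assert len(out) == len(toks)
        seen = set()
        for span, _cls in out:
            key = (span.line_start, span.col_start, span.line_end, span.col_end)
            assert key not in seen
            seen.add(key)

    def test_classification_stable_under_render(self, corpus_model):
        from antimonykit import parse, render

        rendered = render(parse(corpus_model).ast)
        first = sorted(cls for _s, cls in classify_tokens(corpus_model))
        second = sorted(cls for _s, cls in classify_tokens(rendered))
        assert first == second


class TestCoverage:
    def test_partition(self):
        cov = annotation_coverage(ANNOTATED)
        assert cov.annotated == ["BLL"]
        assert set(cov.unannotated) == {"J0", "cell"}

    def test_fully_unannotated(self):
        cov = annotation_coverage("S = 1\nJ: S => ; 1\n")
        assert cov.annotated == []

    def test_apply_annotation_moves_element(self):
        hit = AnnotationHit(
            "chebi", "CHEBI:17234", "glucose", "https://identifiers.org/chebi/CHEBI:17234"
        )
        before = annotation_coverage(ANNOTATED)
        assert "cell" in before.unannotated
        after_doc = apply_annotation(ANNOTATED, "cell", hit)
        after = annotation_coverage(after_doc)
        assert "cell" in after.annotated
        assert "cell" not in after.unannotated

    def test_mode_selects_highlight_set(self):
        annotated_mode = annotation_coverage(ANNOTATED, "highlight-annotated")
        unannotated_mode = annotation_coverage(ANNOTATED, "highlight-unannotated")
        assert annotated_mode.highlighted() == ["BLL"]
        assert set(unannotated_mode.highlighted()) == {"J0", "cell"}
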