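"""Knowledge-source ranking, querying and annotation statements."""

import pytest

from antimonykit import parse
from antimonykit.annotations import (
    AnnotationHit,
    OfflineFixtureBackend,
    QueryError,
    SOURCE_REGISTRY,
    apply_annotation,
    query_source,
    rank_sources,
)
from antimonykit.sbml import antimony_to_sbml, sbml_to_antimony

TYPE_TAGS = [
    "species",
    "parameter",
    "compartment",
    "reaction",
    "function",
    "model",
    "unit",
    "event",
    "unknown",
]

FIXTURES = {
    "glucose": [
        {"source": "chebi", "termId": "CHEBI:17234", "label": "glucose"},
        {"source": "chebi", "termId": "CHEBI:4167", "label": "D-glucopyranose"},
    ],
    "phosphotransfer": [
        {"source": "rhea", "termId": "RHEA:12345", "label": "phosphotransfer"},
    ],
}


class TestRanking:
    def test_species_puts_chebi_first_and_flagged(self):
        ranked = rank_sources("species")
        assert ranked[0][0].id == "chebi"
        assert ranked[0][1] is True

    def test_reaction_puts_rhea_first_and_flagged(self):
        ranked = rank_sources("reaction")
        assert ranked[0][0].id == "rhea"
        assert ranked[0][1] is True

    def test_unknown_type_flags_nothing(self):
        ranked = rank_sources("unknown")
        assert all(flag is False for _s, flag in ranked)
        assert [s.id for s, _f in ranked] == [s.id for s in SOURCE_REGISTRY]

    @pytest.mark.parametrize("tag", TYPE_TAGS)
    def test_every_source_returned_exactly_once(self, tag):
        ranked = rank_sources(tag)
        assert sorted(s.id for s, _f in ranked) == sorted(s.id for s in SOURCE_REGISTRY)
        # appropriate sources strictly precede inappropriate ones
        flags = [f for _s, f in ranked]
        assert flags == sorted(flags, reverse=True)


class TestQuery:
    def test_offline_backend_echoes_fixture_hits(self):
        backend = OfflineFixtureBackend(FIXTURES)
        hits = query_source("chebi", "glucose", backend)
        assert [h.term_id for h in hits] == ["CHEBI:17234", "CHEBI:4167"]
        assert hits[0].uri == "https://identifiers.org/chebi/CHEBI:17234"

    def test_empty_query_skips_backend(self):
        class Exploding:
            def search(self, source_id, text):
                raise AssertionError("backend must not be called")

        assert query_source("chebi", "   ", Exploding()) == []

    def test_backend_failure_is_query_error_not_empty(self):
        class Failing:
            def search(self, source_id, text):
                raise OSError("connection reset")

        with pytest.raises(QueryError):
            query_source("chebi", "glucose", Failing())

    def test_limit_caps_hits(self):
        many = {"q": [
            {"source": "chebi", "termId": f"CHEBI:{i}", "label": str(i)}
            for i in range(50)
        ]}
        hits = query_source("chebi", "q", OfflineFixtureBackend(many), limit=20)
        assert len(hits) == 20


class TestApply:
    DOC = (
        "species BLL\n"
        "BLL = 1\n"
        "k = 1\n"
        "J0: BLL => ; k*BLL\n"
    )
    HIT = AnnotationHit(
        "chebi", "CHEBI:28262", "ligand", "https://identifiers.org/chebi/CHEBI:28262"
    )

    def test_statement_appended_at_bottom(self):
        new = apply_annotation(self.DOC, "BLL", self.HIT)
        lines = [l for l in new.split("\n") if l]
        assert lines[-1] == 'BLL identity "https://identifiers.org/chebi/CHEBI:28262"'
        assert parse(new).errors == []

    def test_reapplying_identical_hit_is_noop(self):
        once = apply_annotation(self.DOC, "BLL", self.HIT)
        twice = apply_annotation(once, "BLL", self.HIT)
        assert once == twice

    def test_unresolvable_element_raises(self):
        with pytest.raises(KeyError):
            apply_annotation(self.DOC, "ghost", self.HIT)

    def test_annotation_inside_model_block_stays_in_block(self):
        doc = "model m\n  species P\n  P = 1\nend\n"
        new = apply_annotation(doc, "P", self.HIT)
        result = parse(new)
        assert result.errors == []
        model = next(result.ast.find_all("modelDef"))
        assert any(n.kind == "annotationStmt" for n in model.children)

    def test_annotation_survives_sbml_round_trip(self):
        annotated = apply_annotation(self.DOC, "BLL", self.HIT)
        xml, _report = antimony_to_sbml(parse(annotated).ast)
        back, _r = sbml_to_antimony(xml)
        assert 'BLL identity "https://identifiers.org/chebi/CHEBI:28262"' in back

    def test_pair_set_preserved_both_ways(self):
        annotated = apply_annotation(self.DOC, "BLL", self.HIT)
        annotated = apply_annotation(
            annotated,
            "J0",
            AnnotationHit(
                "rhea", "RHEA:12345", "rx", "https://identifiers.org/rhea/RHEA:12345"
            ),
        )
        xml, _report = antimony_to_sbml(parse(annotated).ast)
        back, _r = sbml_to_antimony(xml)

        def pairs(doc):
            out = set()
            for node in parse(doc).ast.find_all("annotationStmt"):
                for uri in node.get("uris"):
                    out.add((node.get("name"), uri))
            return out

        assert pairs(annotated) == pairs(back)
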