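"""Antimony ↔ SBML translation, equivalence checking and pair sync."""

import xml.etree.ElementTree as ET

import pytest

from antimonykit import parse
from antimonykit.sbml import (
    ConversionError,
    SyncState,
    antimony_to_sbml,
    sbml_to_antimony,
    semantic_equivalent,
    sync_pair,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"

MASS_ACTION = (
    "compartment cell\n"
    "cell = 1\n"
    "species S1 in cell, S2 in cell\n"
    "S1 = 10\n"
    "S2 = 0\n"
    "k1 = 0.5\n"
    "J0: S1 => S2; cell*k1*S1\n"
)

MINIMAL_FBC = (
    '<?xml version="1.0" encoding="UTF-8"?>\n'
    f'<sbml xmlns="{SBML_NS}" '
    'xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2" '
    'level="3" version="1" fbc:required="false">\n'
    '  <model id="m">\n'
    "    <listOfCompartments>\n"
    '      <compartment id="c" size="1" constant="true"/>\n'
    "    </listOfCompartments>\n"
    "    <listOfSpecies>\n"
    '      <species id="A" compartment="c" initialConcentration="1" '
    'boundaryCondition="false" constant="false" hasOnlySubstanceUnits="false"/>\n'
    "    </listOfSpecies>\n"
    '    <fbc:listOfObjectives fbc:activeObjective="obj1"/>\n'
    "  </model>\n"
    "</sbml>\n"
)


def _counts_via_etree(xml: str) -> dict:
    """Independent structural count straight off the XML tree."""
    root = ET.fromstring(xml)

    def count(tag):
        return len(root.findall(f".//{{{SBML_NS}}}{tag}"))

    return {
        "species": count("species"),
        "reactions": count("reaction"),
        "parameters": count("parameter"),
        "compartments": count("compartment"),
    }


class TestAntimonyToSbml:
    def test_one_reaction_structure(self):
        xml, _report = antimony_to_sbml(parse(MASS_ACTION).ast)
        counts = _counts_via_etree(xml)
        assert counts == {
            "species": 2,
            "reactions": 1,
            "parameters": 1,
            "compartments": 1,
        }
        root = ET.fromstring(xml)
        rx = root.find(f".//{{{SBML_NS}}}reaction")
        assert rx.get("reversible") == "false"
        stoichs = [
            sr.get("stoichiometry")
            for sr in root.findall(f".//{{{SBML_NS}}}speciesReference")
        ]
        assert stoichs == ["1", "1"]

    def test_comment_is_lossy_but_semantically_inert(self):
        with_comment = MASS_ACTION + "// just a note\n"
        xml_plain, report_plain = antimony_to_sbml(parse(MASS_ACTION).ast)
        xml_comment, report_comment = antimony_to_sbml(parse(with_comment).ast)
        assert xml_plain == xml_comment
        assert len(report_plain.lossy_items) == 0
        assert len(report_comment.lossy_items) == 1
        assert "note" in report_comment.lossy_items[0][1]

    def test_empty_model(self):
        xml, _report = antimony_to_sbml(parse("").ast)
        root = ET.fromstring(xml)
        assert root.find(f"{{{SBML_NS}}}model") is not None

    def test_error_diagnostics_block_conversion(self):
        # k has no value: an error-severity diagnostic
        with pytest.raises(ConversionError) as exc:
            antimony_to_sbml(parse("S = 1\nJ: S => ; k*S\n").ast)
        assert any(d.rule_id == "PRM001" for d in exc.value.diagnostics)

    def test_identical_input_yields_identical_bytes(self):
        a, _r1 = antimony_to_sbml(parse(MASS_ACTION).ast)
        b, _r2 = antimony_to_sbml(parse(MASS_ACTION).ast)
        assert a == b


class TestSbmlToAntimony:
    def test_round_trip_of_own_output(self):
        xml, _report = antimony_to_sbml(parse(MASS_ACTION).ast)
        ant, _report2 = sbml_to_antimony(xml)
        assert parse(ant).errors == []
        equal, diffs = semantic_equivalent(MASS_ACTION, ant)
        assert equal, diffs

    def test_non_sbml_xml_names_root_element(self):
        with pytest.raises(ConversionError) as exc:
            sbml_to_antimony("<notes><x/></notes>")
        assert "notes" in str(exc.value)

    def test_fbc_package_skipped_with_warning(self):
        ant, report = sbml_to_antimony(MINIMAL_FBC)
        assert parse(ant).errors == []
        assert any("fbc" in w or "listOfObjectives" in w for w in report.warnings)
        assert "A" in ant


class TestSemanticEquivalence:
    def test_statement_order_is_irrelevant(self):
        shuffled = "\n".join(reversed(MASS_ACTION.strip().split("\n"))) + "\n"
        equal, diffs = semantic_equivalent(MASS_ACTION, shuffled)
        assert equal, diffs

    def test_stoichiometry_change_detected(self):
        a = "A = 1\nB = 0\nk = 1\nJ: 2 A => B; k*A\n"
        b = a.replace("2 A", "A")
        equal, diffs = semantic_equivalent(a, b)
        assert not equal
        assert any("A" in d for d in diffs)

    def test_commutativity_normalization(self):
        a = "A = 1\nB = 0\nk = 1\nc = 2\nJ: A => B; k*c*A\n"
        b = "A = 1\nB = 0\nk = 1\nc = 2\nJ: A => B; A*k*c\n"
        equal, diffs = semantic_equivalent(a, b)
        assert equal, diffs

    def test_unparseable_side_raises_with_diagnostics(self):
        with pytest.raises(ConversionError):
            semantic_equivalent("S = 1\nJ: S => ; kq*S\n", "A = 1\n")


class TestRoundTripProperty:
    def test_generated_corpus_round_trips(self, generated_corpus):
        for text in generated_corpus:
            xml, _report = antimony_to_sbml(parse(text).ast)
            ant, _r = sbml_to_antimony(xml)
            equal, diffs = semantic_equivalent(text, ant)
            assert equal, (text, diffs)

    def test_corpus_counts_agree_between_routes(self, generated_corpus):
        """Source-side symbol counts equal element counts in the emitted XML
        (counted independently with xml.etree)."""
        from antimonykit import build_symbol_table

        for text in generated_corpus:
            table = build_symbol_table(parse(text).ast)
            scope = table.scopes["__main"]
            xml, _report = antimony_to_sbml(parse(text).ast)
            counts = _counts_via_etree(xml)
            species = [s for s in scope.symbols.values() if s.type == "species"]
            params = [s for s in scope.symbols.values() if s.type == "parameter"]
            assert counts["species"] == len(species)
            assert counts["parameters"] == len(params)
            assert counts["reactions"] == len(scope.reactions)


class TestSyncPair:
    def _paths(self, tmp_path):
        return str(tmp_path / "m.ant"), str(tmp_path / "m.xml")

    def test_ant_edit_propagates_species(self, tmp_path):
        ant_path, xml_path = self._paths(tmp_path)
        state = SyncState(ant_path, xml_path)
        state, _report = sync_pair(state, "ant", MASS_ACTION)
        edited = MASS_ACTION + "species S3 in cell\nS3 = 1\n"
        state, _report = sync_pair(state, "ant", edited)
        xml = (tmp_path / "m.xml").read_text()
        assert 'id="S3"' in xml
        assert state.last_writer == "ant"

    def test_blocked_propagation_leaves_partner_untouched(self, tmp_path):
        ant_path, xml_path = self._paths(tmp_path)
        state = SyncState(ant_path, xml_path)
        state, _report = sync_pair(state, "ant", MASS_ACTION)
        xml_before = (tmp_path / "m.xml").read_text()
        bad = MASS_ACTION + "J1: S1 => S2; mystery_k*S1\n"  # PRM001 error
        state, report = sync_pair(state, "ant", bad)
        assert any("refused" in w for w in report.warnings)
        assert (tmp_path / "m.xml").read_text() == xml_before

    def test_identical_resync_is_noop(self, tmp_path):
        ant_path, xml_path = self._paths(tmp_path)
        state = SyncState(ant_path, xml_path)
        state, _report = sync_pair(state, "ant", MASS_ACTION)
        state2, report = sync_pair(state, "ant", MASS_ACTION)
        assert state2 is state
        assert any("no-op" in w for w in report.warnings)

    def test_xml_edit_propagates_back(self, tmp_path):
        ant_path, xml_path = self._paths(tmp_path)
        state = SyncState(ant_path, xml_path)
        state, _report = sync_pair(state, "ant", MASS_ACTION)
        xml = (tmp_path / "m.xml").read_text().replace('initialConcentration="10"', 'initialConcentration="42"')
        state, _report = sync_pair(state, "xml", xml)
        assert "S1 = 42" in (tmp_path / "m.ant").read_text()
        assert state.last_writer == "xml"
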