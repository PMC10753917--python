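"""Symbol-table construction, scoped resolution and import handling."""

import pytest

from antimonykit import build_symbol_table, parse, render, resolve_imports, resolve_symbol
from antimonykit.symbols import MAIN_SCOPE


class TestTyping:
    def test_reaction_symbols(self):
        table = build_symbol_table(parse("J0: Yp => Ypp; k1*Yp").ast)
        assert table.lookup("Yp").type == "species"
        assert table.lookup("Ypp").type == "species"
        assert table.lookup("k1").type == "parameter"
        assert table.lookup("J0").type == "reaction"

    def test_bare_assignment_defaults_to_parameter(self):
        table = build_symbol_table(parse("glucose_rate = 3").ast)
        sym = table.lookup("glucose_rate")
        assert sym.type == "parameter"
        assert sym.init_value is not None
        assert sym.init_value.children[0].text == "3"

    def test_empty_document_has_main_scope(self):
        table = build_symbol_table(parse("").ast)
        assert list(table.scopes) == [MAIN_SCOPE]
        assert table.scopes[MAIN_SCOPE].symbols == {}

    def test_keyword_declarations(self):
        src = "species A in cell\ncompartment cell\nfunction f(x)\n  x\nend\nunit mM = 1\nE0: at A > 1: A = 0\n"
        table = build_symbol_table(parse(src).ast)
        assert table.lookup("A").type == "species"
        assert table.lookup("A").compartment_of == "cell"
        assert table.lookup("cell").type == "compartment"
        assert table.lookup("f").type == "function"
        assert table.lookup("mM").type == "unit"
        assert table.lookup("E0").type == "event"

    def test_structural_evidence_beats_assignment(self):
        # an assigned name later used as a reactant is a species, not a
        # parameter, and records no conflict
        table = build_symbol_table(parse("S = 1\nJ: S => ; k*S").ast)
        sym = table.lookup("S")
        assert sym.type == "species"
        assert sym.conflicts == []

    def test_conflicting_structural_evidence_recorded(self):
        table = build_symbol_table(parse("J: S => ; k*S\ncompartment S").ast)
        sym = table.lookup("S")
        assert sym.type == "species"  # first evidence wins
        assert len(sym.conflicts) == 1
        assert sym.conflicts[0][0] == "compartment"

    def test_table_stable_under_render(self, corpus_model):
        first = build_symbol_table(parse(corpus_model).ast)
        second = build_symbol_table(parse(render(parse(corpus_model).ast)).ast)
        assert {
            (s.name, s.type, s.scope) for s in first.all_symbols()
        } == {(s.name, s.type, s.scope) for s in second.all_symbols()}


class TestResolution:
    NESTED = (
        "outer_k = 1\n"
        "model mid\n"
        "  mid_k = 2\n"
        "  model inner\n"
        "    inner_k = 3\n"
        "  end\n"
        "end\n"
    )

    def test_direct_hit(self):
        table = build_symbol_table(parse("k1 = 1\nJ0: A => ; k1*A").ast)
        assert resolve_symbol(table, "k1", MAIN_SCOPE).type == "parameter"

    def test_missing_symbol_is_none(self):
        table = build_symbol_table(parse("k1 = 1").ast)
        assert resolve_symbol(table, "nosuch", MAIN_SCOPE) is None

    def test_unknown_scope_raises(self):
        table = build_symbol_table(parse("k1 = 1").ast)
        with pytest.raises(LookupError):
            resolve_symbol(table, "k1", "ghost_scope")

    def test_scope_chain_fallback_matches_enumeration(self):
        """Inner scopes fall back outward exactly along the lexical chain."""
        table = build_symbol_table(parse(self.NESTED).ast)
        chains = {
            "inner": ["inner", "mid", MAIN_SCOPE],
            "mid": ["mid", MAIN_SCOPE],
            MAIN_SCOPE: [MAIN_SCOPE],
        }
        for scope, chain in chains.items():
            for name in ("inner_k", "mid_k", "outer_k"):
                # brute-force oracle: first scope in the chain holding name
                expected = None
                for s in chain:
                    if name in table.scopes[s].symbols:
                        expected = table.scopes[s].symbols[name]
                        break
                assert resolve_symbol(table, name, scope) is expected


class TestImports:
    FILES = {
        "mm.ant": "function MM(S, Vm, Km)\n  Vm*S/(Km + S)\nend\n",
        "shared.ant": "shared_k = 1\n",
        "a.ant": 'import "shared.ant"\n',
        "b.ant": 'import "shared.ant"\n',
        "both.ant": 'import "a.ant"\nimport "b.ant"\n',
        "self.ant": 'import "self.ant"\n',
    }

    def loader(self, calls=None):
        def load(path):
            if calls is not None:
                calls.append(path)
            return self.FILES[path]

        return load

    def test_imported_function_resolvable(self):
        table = resolve_imports(parse('import "mm.ant"\n').ast, self.loader())
        sym = table.lookup("MM")
        assert sym is not None and sym.type == "function"

    def test_self_import_reports_cycle_once(self):
        table = resolve_imports(parse('import "self.ant"\n').ast, self.loader())
        cycle_errors = [e for e in table.import_errors if "cycle" in e.message]
        assert len(cycle_errors) == 1

    def test_shared_import_loaded_once(self):
        calls: list[str] = []
        resolve_imports(parse('import "both.ant"\n').ast, self.loader(calls))
        assert calls.count("shared.ant") == 1

    def test_unreadable_path_reported(self):
        table = resolve_imports(parse('import "missing.ant"\n').ast, self.loader())
        assert any("missing.ant" in e.message for e in table.import_errors)
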