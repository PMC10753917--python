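"""Shared fixtures: a hand-written model corpus plus generated networks."""

from __future__ import annotations

import pytest

from antimonykit.fixtures import FixtureSpec, generate_fixture

# small corpus covering the supported statement surface: reactions with both
# arrows and stoichiometries, declarations, rules, events, functions, units,
# display names, annotations, fixed species and model blocks
CORPUS: dict[str, str] = {
    "combustion": "O2 + 2 H2 -> 2 H2O\n",
    "mass_action": (
        "compartment cell\n"
        "cell = 1\n"
        "species S1 in cell, S2 in cell\n"
        "S1 = 10\n"
        "S2 = 0\n"
        "k1 = 0.5\n"
        "J0: S1 => S2; cell*k1*S1\n"
    ),
    "annotated": (
        "species BLL, DL, ILL\n"
        "BLL = 1\n"
        "DL = 2\n"
        "ILL = 0\n"
        "kf = 0.1\n"
        "React1: BLL + DL => ILL; kf*BLL*DL\n"
        'BLL is "basal ligand-bound form"\n'
        'BLL identity "https://identifiers.org/chebi/CHEBI:28262"\n'
    ),
    "rules_events": (
        "species P\n"
        "P = 0\n"
        "ksyn = 2\n"
        "kdeg = 0.1\n"
        "total := P + ksyn\n"
        "J0: => P; ksyn\n"
        "J1: P => ; kdeg*P\n"
        "E0: at P > 10: kdeg = 0.5\n"
    ),
    "functions": (
        "function MM(S, Vm, Km)\n"
        "  Vm*S/(Km + S)\n"
        "end\n"
        "species G\n"
        "G = 5\n"
        "Vm = 1\n"
        "Km = 0.4\n"
        "J0: G => ; MM(G, Vm, Km)\n"
    ),
    "fixed_and_rate": (
        "species $X0, S\n"
        "X0 = 10\n"
        "S = 0\n"
        "k = 0.2\n"
        "J0: $X0 => S; k*X0\n"
        "z = 1\n"
        "z' = 0.1*z\n"
    ),
    "model_block": (
        "model osc\n"
        "  species A, B\n"
        "  A = 1\n"
        "  B = 0\n"
        "  k1 = 3\n"
        "  J0: A -> B; k1*A\n"
        "end\n"
    ),
}


@pytest.fixture(params=sorted(CORPUS))
def corpus_model(request) -> str:
    return CORPUS[request.param]


@pytest.fixture(scope="session")
def generated_corpus() -> list[str]:
    """Comment-free seeded networks used by round-trip property tests."""
    models = []
    for seed in range(30):
        text, _manifest = generate_fixture(FixtureSpec(4, 3, (), seed))
        models.append(
            "\n".join(
                line for line in text.split("\n") if not line.strip().startswith("//")
            )
        )
    return models
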