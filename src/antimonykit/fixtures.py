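"""Deterministic synthetic-model generation with diagnostic fault injection,
plus a pluggable BioModels fetcher.

``generate_fixture`` builds a seeded pseudo-random mass-action reaction
network in which every symbol is initialized (a *clean* model produces zero
diagnostics), then injects one minimal fault per requested rule id.  The
manifest records which diagnostics the injected faults must produce — it is
the oracle the diagnostics engine is tested against — including the
unavoidable cascades (e.g. deleting a species initialization also makes any
kinetic law referencing it fire the uninitialized-species reaction rule).

``synthetic_chemotaxis_model`` builds a stand-in for the bacterial
chemotaxis phosphorelay network (receptor-complex assembly, complex
phosphorylation, and phosphotransfer to the response regulator Y): a
SYNTHETIC model constructed to the published network's shape — 32 reactions,
of which exactly 7 phosphorylate Y — for offline end-to-end testing; it is
not the curated BioModels entry.
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field
from typing import Optional, Protocol


@dataclass(frozen=True)
class FixtureSpec:
    n_species: int
    n_reactions: int
    faults: tuple[str, ...] = ()
    seed: int = 0


@dataclass
class FixtureManifest:
    expected_diagnostics: list[tuple[str, str]]  # (rule id, offending symbol)
    cascade_rules: list[str]  # rules that may additionally fire
    model_text: str = ""


class FixtureError(ValueError):
    pass


def generate_fixture(spec: FixtureSpec) -> tuple[str, FixtureManifest]:
    """Seeded reaction-network fixture with injected faults.

    The same spec always yields byte-identical text.  Unknown fault rule ids
    raise :class:`FixtureError`.
    """
    if spec.n_species < 1:
        raise FixtureError("need at least one species")
    if spec.n_reactions < 0:
        raise FixtureError("negative reaction count")
    for fault in spec.faults:
        if fault not in _INJECTORS:
            raise FixtureError(f"unknown fault rule id '{fault}'")

    rng = random.Random(spec.seed)
    species = [f"S{i}" for i in range(spec.n_species)]
    lines: list[str] = [f"// synthetic fixture seed={spec.seed}"]
    for s in species:
        lines.append(f"{s} = {rng.randint(1, 20)}")
    lines.append(f"species {', '.join(species)}")
    for j in range(spec.n_reactions):
        n_r = rng.choice([1, 1, 2])
        n_p = rng.choice([1, 1, 2])
        reactants = rng.sample(species, min(n_r, len(species)))
        products = rng.sample(species, min(n_p, len(species)))
        arrow = rng.choice(["=>", "=>", "->"])
        k = f"k_J{j}"
        law = "*".join([k] + reactants)
        lines.append(f"{k} = {round(rng.uniform(0.1, 5.0), 3)}")
        lines.append(f"J{j}: {' + '.join(reactants)} {arrow} {' + '.join(products)}; {law}")

    manifest = FixtureManifest([], [])
    ctx = _InjectCtx(species=species, n_reactions=spec.n_reactions, rng=rng)
    for fault in spec.faults:
        _INJECTORS[fault](lines, manifest, ctx)
    manifest.model_text = "\n".join(lines) + "\n"
    return manifest.model_text, manifest


@dataclass
class _InjectCtx:
    species: list[str]
    n_reactions: int
    rng: random.Random

    def need_reaction(self, rule: str) -> str:
        if self.n_reactions < 1:
            raise FixtureError(f"fault {rule} needs a base model with >= 1 reaction")
        return "J0"

    def need_species(self, rule: str, n: int) -> list[str]:
        if len(self.species) < n:
            raise FixtureError(f"fault {rule} needs >= {n} species")
        return self.species[:n]


def _inj_spc001(lines, manifest, ctx):
    lines.append("species X_noinit")
    manifest.expected_diagnostics.append(("SPC001", "X_noinit"))


def _inj_spc002(lines, manifest, ctx):
    (s0,) = ctx.need_species("SPC002", 1)
    lines.append(f"{s0} = 99")
    manifest.expected_diagnostics.append(("SPC002", s0))


def _inj_prm001(lines, manifest, ctx):
    s0, s1 = ctx.need_species("PRM001", 2)
    lines.append(f"J_prm: {s0} => {s1}; k_missing*{s0}")
    manifest.expected_diagnostics.append(("PRM001", "k_missing"))


def _inj_prm002(lines, manifest, ctx):
    ctx.need_reaction("PRM002")
    lines.append("k_J0 = 7.7")
    manifest.expected_diagnostics.append(("PRM002", "k_J0"))


def _inj_cpt001(lines, manifest, ctx):
    lines.append("compartment c_noinit")
    manifest.expected_diagnostics.append(("CPT001", "c_noinit"))


def _inj_cpt002(lines, manifest, ctx):
    lines.append("compartment c_twice")
    lines.append("c_twice = 1")
    lines.append("c_twice = 2")
    manifest.expected_diagnostics.append(("CPT002", "c_twice"))


def _inj_rea001(lines, manifest, ctx):
    (s0,) = ctx.need_species("REA001", 1)
    lines.append("species U_noinit")
    lines.append("k_rea = 1")
    lines.append(f"J_rea: U_noinit => {s0}; k_rea*U_noinit")
    manifest.expected_diagnostics.append(("REA001", "U_noinit"))
    manifest.cascade_rules.append("SPC001")


def _inj_rea002(lines, manifest, ctx):
    j0 = ctx.need_reaction("REA002")
    s0, s1 = ctx.need_species("REA002", 2)
    lines.append("k_rea2 = 1")
    lines.append(f"J_rea2: {s0} => {s1}; k_rea2*{j0}")
    manifest.expected_diagnostics.append(("REA002", j0))


def _inj_rl001(lines, manifest, ctx):
    s0, s1 = ctx.need_species("RL001", 2)
    lines.append("k_rl = 1")
    lines.append(f"J_rl: {s0} => {s1}; k_rl*{s0}")
    lines.append(f"{s0}' = 5")
    manifest.expected_diagnostics.append(("RL001", s0))
    manifest.cascade_rules.append("SPC002")


def _inj_rl002(lines, manifest, ctx):
    lines.append("q_rate' = 1")
    lines.append("q_rate' = 2")
    manifest.expected_diagnostics.append(("RL002", "q_rate"))


def _inj_evt001(lines, manifest, ctx):
    (s0,) = ctx.need_species("EVT001", 1)
    lines.append(f"Ev_dup: at {s0} > 100: {s0} = 1")
    lines.append(f"Ev_dup: at {s0} > 200: {s0} = 2")
    manifest.expected_diagnostics.append(("EVT001", "Ev_dup"))


def _inj_fun001(lines, manifest, ctx):
    lines.append("function f_unused(aa, bb)")
    lines.append("  aa + 1")
    lines.append("end")
    manifest.expected_diagnostics.append(("FUN001", "bb"))


def _inj_fun002(lines, manifest, ctx):
    (s0,) = ctx.need_species("FUN002", 1)
    lines.append(f"z_f2 = ghost_fn({s0})")
    manifest.expected_diagnostics.append(("FUN002", "ghost_fn"))


def _inj_fun003(lines, manifest, ctx):
    s0, s1 = ctx.need_species("FUN003", 2)
    lines.append("function f_arity(aa)")
    lines.append("  aa*2")
    lines.append("end")
    lines.append(f"z_f3 = f_arity({s0}, {s1})")
    manifest.expected_diagnostics.append(("FUN003", "f_arity"))


def _inj_fun004(lines, manifest, ctx):
    j0 = ctx.need_reaction("FUN004")
    lines.append("function f_typed(aa)")
    lines.append("  aa + 0")
    lines.append("end")
    lines.append(f"z_f4 = f_typed({j0})")
    manifest.expected_diagnostics.append(("FUN004", j0))


def _inj_fun005(lines, manifest, ctx):
    (s0,) = ctx.need_species("FUN005", 1)
    lines.append(f"function {s0}(aa)")
    lines.append("  aa")
    lines.append("end")
    manifest.expected_diagnostics.append(("FUN005", s0))


def _inj_mdl001(lines, manifest, ctx):
    lines.append("m_bad: ghost_model(1)")
    manifest.expected_diagnostics.append(("MDL001", "ghost_model"))


def _inj_mdl002(lines, manifest, ctx):
    lines.append("model mdl_uno(aa)")
    lines.append("  aa = 1")
    lines.append("end")
    lines.append("m_arity: mdl_uno(1, 2)")
    manifest.expected_diagnostics.append(("MDL002", "mdl_uno"))


def _inj_mdl003(lines, manifest, ctx):
    lines.append("model mdl_spc(ss)")
    lines.append("  k_in = 1")
    lines.append("  J_in: ss => ; k_in*ss")
    lines.append("end")
    lines.append("k_glob = 1")
    lines.append("m_typed: mdl_spc(k_glob)")
    manifest.expected_diagnostics.append(("MDL003", "k_glob"))


def _inj_gen001(lines, manifest, ctx):
    (s0,) = ctx.need_species("GEN001", 1)
    lines.append(f'{s0} is "alpha"')
    lines.append(f'{s0} is "beta"')
    manifest.expected_diagnostics.append(("GEN001", s0))


def _inj_gen002(lines, manifest, ctx):
    (s0,) = ctx.need_species("GEN002", 1)
    lines.append(f"compartment {s0}")
    manifest.expected_diagnostics.append(("GEN002", s0))


def _inj_gen003(lines, manifest, ctx):
    lines.append("= 4")
    manifest.expected_diagnostics.append(("GEN003", "="))


def _inj_gen004(lines, manifest, ctx):
    s0, s1 = ctx.need_species("GEN004", 2)
    lines.append(f"{s0} => {s1};")
    manifest.expected_diagnostics.append(("GEN004", ";"))


_INJECTORS = {
    "SPC001": _inj_spc001,
    "SPC002": _inj_spc002,
    "PRM001": _inj_prm001,
    "PRM002": _inj_prm002,
    "CPT001": _inj_cpt001,
    "CPT002": _inj_cpt002,
    "REA001": _inj_rea001,
    "REA002": _inj_rea002,
    "RL001": _inj_rl001,
    "RL002": _inj_rl002,
    "EVT001": _inj_evt001,
    "FUN001": _inj_fun001,
    "FUN002": _inj_fun002,
    "FUN003": _inj_fun003,
    "FUN004": _inj_fun004,
    "FUN005": _inj_fun005,
    "MDL001": _inj_mdl001,
    "MDL002": _inj_mdl002,
    "MDL003": _inj_mdl003,
    "GEN001": _inj_gen001,
    "GEN002": _inj_gen002,
    "GEN003": _inj_gen003,
    "GEN004": _inj_gen004,
}


# ---------------------------------------------------------------------------
# synthetic chemotaxis phosphorelay stand-in
# ---------------------------------------------------------------------------

_COMPLEXES = ["WAA", "WWAA", "TTAA", "TTWAA", "TTWWAA"]


def synthetic_chemotaxis_model() -> str:
    """SYNTHETIC chemotaxis phosphorelay network (not the curated entry).

    Receptor complexes assemble from W/AA/TT subunits, are phosphorylated and
    dephosphorylated, and transfer phosphate to the response regulator Y
    (Y -> Yp -> Ypp).  Shaped to the published network's headline structure:
    32 mass-action reactions, exactly 7 of which phosphorylate Y (i.e. have
    Y as reactant and Yp as product).
    """
    rng = random.Random(200)
    reactions: list[tuple[str, str, str]] = []  # (lhs, arrow, rhs)

    # complex assembly and disassembly (10)
    assembly = [
        ("W + AA", "WAA"),
        ("WAA + W", "WWAA"),
        ("TT + AA", "TTAA"),
        ("TTAA + W", "TTWAA"),
        ("TTWAA + W", "TTWWAA"),
    ]
    for lhs, rhs in assembly:
        reactions.append((lhs, "=>", rhs))
    for lhs, rhs in assembly:
        reactions.append((rhs, "=>", lhs))

    # complex (de)phosphorylation (10)
    for m in _COMPLEXES:
        reactions.append((m, "=>", f"{m}p"))
    for m in _COMPLEXES:
        reactions.append((f"{m}p", "=>", m))

    # phosphorylation of the response regulator Y (7)
    reactions.append(("Y", "=>", "Yp"))
    for m in _COMPLEXES:
        reactions.append((f"Y + {m}p", "=>", f"Yp + {m}"))
    reactions.append(("Y + CheAp", "=>", "Yp + CheA"))

    # remaining turnover (5)
    reactions.append(("Yp", "=>", "Y"))
    reactions.append(("Yp + TTWWAAp", "=>", "Ypp + TTWWAA"))
    reactions.append(("Ypp", "=>", "Yp"))
    reactions.append(("CheA", "=>", "CheAp"))
    reactions.append(("CheAp", "=>", "CheA"))

    species = sorted(
        {
            name
            for lhs, _a, rhs in reactions
            for name in re.split(r"\s*\+\s*", lhs + " + " + rhs)
        }
    )
    lines = ["compartment cell", "cell = 1"]
    for s in species:
        lines.append(f"species {s} in cell")
        lines.append(f"{s} = {round(rng.uniform(0.1, 10.0), 2)}")
    for i, (lhs, arrow, rhs) in enumerate(reactions):
        k = f"r{i}_k1"
        factors = "*".join(re.split(r"\s*\+\s*", lhs))
        lines.append(f"{k} = {round(rng.uniform(0.01, 2.0), 3)}")
        lines.append(f"J{i}: {lhs} {arrow} {rhs}; cell*{k}*{factors}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# BioModels access
# ---------------------------------------------------------------------------

class NotFoundError(LookupError):
    pass


class FetchError(RuntimeError):
    """Network failure fetching a model (retriable)."""


class BioModelsClient(Protocol):
    def get_sbml(self, model_number: int) -> str:
        ...

    def search(self, text: str) -> list[dict]:
        ...


@dataclass
class RecordedBioModelsClient:
    """Replay client: canned {model number: SBML text} plus a search index."""

    models: dict[int, str] = field(default_factory=dict)
    search_index: dict[str, list[dict]] = field(default_factory=dict)

    def get_sbml(self, model_number: int) -> str:
        if model_number not in self.models:
            raise NotFoundError(f"no recorded model {model_number}")
        return self.models[model_number]

    def search(self, text: str) -> list[dict]:
        return self.search_index.get(text, [])


class RestBioModelsClient:
    """Live client for the BioModels REST API; requires network access."""

    BASE = "https://www.ebi.ac.uk/biomodels"

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def get_sbml(self, model_number: int) -> str:
        import urllib.error
        import urllib.request

        accession = f"BIOMD{model_number:010d}"
        url = f"{self.BASE}/model/download/{accession}?filename={accession}_url.xml"
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                return resp.read().decode()
        except urllib.error.HTTPError as exc:
            if exc.code == 404:
                raise NotFoundError(f"model {accession} not found") from exc
            raise FetchError(str(exc)) from exc
        except (urllib.error.URLError, OSError) as exc:
            raise FetchError(str(exc)) from exc

    def search(self, text: str) -> list[dict]:
        import json as _json
        import urllib.error
        import urllib.parse
        import urllib.request

        url = f"{self.BASE}/search?query={urllib.parse.quote(text)}&format=json"
        try:
            with urllib.request.urlopen(url, timeout=self.timeout) as resp:
                payload = _json.loads(resp.read().decode())
        except (urllib.error.URLError, OSError, ValueError) as exc:
            raise FetchError(str(exc)) from exc
        return payload.get("models", [])


def fetch_biomodel(query: int | str, client: BioModelsClient):
    """Fetch a BioModels entry: an integer returns that model's SBML text, a
    string returns the matching-model candidate list for user selection."""
    if isinstance(query, int):
        if query <= 0:
            raise NotFoundError(f"model number {query} does not exist")
        return client.get_sbml(query)
    return client.search(query)
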