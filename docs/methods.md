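# Methods

This note documents the language model, the analysis rules, the translation
mapping and the synthetic-data generator behind `antimonykit`, together with
the design choices made where more than one reading was defensible.

## Language subset and parsing

The parser is a hand-written recursive-descent implementation over a
dedicated tokenizer. It covers the Antimony statement subset a
reaction-network modeler uses in practice:

- reactions `[label:] n A + m B (-> | =>) products [; law]` — `->` marks a
  reversible, `=>` an irreversible reaction; stoichiometries default to 1;
  either side may be empty (synthesis/degradation); `$X` marks a fixed
  (boundary) species;
- declarations `const|var [species|compartment|formula] name [in C] [= v]`;
- value assignments `x = expr`, assignment rules `x := expr`, rate rules
  `x' = expr`;
- events `[label:] at trigger : target = expr, ...`;
- function definitions `function f(a, b) ... end`, model blocks
  `model m(p) ... end` and modular instantiation `inst: m(args)`;
- `import "file"`, display names `x is "text"`, annotation statements
  `x identity "uri"` (plus the other MIRIAM qualifiers), unit declarations,
  and `//` / `/* */` comments (kept as first-class nodes).

Exotic constructs (submodel deletions, ports, interactions) are rejected
with an ordinary syntax diagnostic. Coordinates are 0-based lines and
half-open column ranges, the convention of mainstream editor protocols.
After a syntax error the parser skips to the next statement boundary
(newline or `;`), so every faulty statement in a file is reported and all
well-formed statements around it survive into the tree. A grammar violation
is never an exception: it becomes a `GEN003` (unexpected token) or `GEN004`
(unexpected newline/EOF) diagnostic with the offending token's span.

The pretty-printer emits one statement per line with single spaces around
arrows and `+` and minimal parentheses; `parse ∘ render` is a structural
fixed point, which the test suite checks over both a hand-written corpus
and generated networks.

## Symbol typing

Every identifier carries exactly one type tag: species, parameter,
compartment, reaction, function, model, unit, event or unknown. Structural
evidence is decisive: reaction participation or a `species` keyword makes a
species; a `compartment` keyword or use after `in` a compartment; labels
and headers type reactions, events, functions and models. A name that is
only ever assigned or used inside expressions defaults to parameter — the
Antimony convention (`glucose_rate = 3` declares a parameter). The first
piece of structural evidence wins; later incompatible structural evidence
is *recorded* as a conflict and surfaced as a diagnostic (`GEN002`, or
`FUN005` when the conflicting use is a function header), never raised.
Scopes nest lexically (`__main` at the root, one scope per model block)
with innermost-first resolution; imports are resolved through a
caller-supplied `path -> text` loader, memoized so shared files parse once,
with cycles reported once instead of recursing.

## Diagnostic catalog

The registry holds 23 rules — 12 errors and 11 warnings — grouped by
element type (Spc, Prm, Cpt, Rea, Rl, Evt, Fun, Mdl, Gen). An *error*
means the model cannot be simulated (e.g. `PRM001`, a parameter with no
value; `FUN003`, a call with the wrong argument count); a *warning* flags
questionable practice (e.g. `SPC002`, silently overriding a species'
value). Interpretations fixed where a one-line rule description left
latitude:

- **"Initialized"** means a literal assignment, assignment rule or rate
  rule anywhere in the scope, regardless of textual order — Antimony files
  are declaration-order-insensitive.
- **`REA002` (invalid arithmetic expression)** fires when a kinetic-law
  *operand* is a non-value symbol (a reaction, model, event or unit name);
  **`FUN004`/`MDL003`** apply the same idea to call/instantiation
  arguments, under a compatibility lattice in which `unknown` is compatible
  with everything and species/parameter/compartment are mutually
  incompatible.
- **`RL001`** fires when a rate-rule variable is a species that also
  participates in a reaction without being fixed (`$`/`const`) — the ODE
  implied by the rule would conflict with the reaction's.
- **"Unused parameter" (`FUN001`)** applies to function formals only.
- **Model formals** are exempt from the no-initial-value rules: they are
  bound at instantiation.
- **Cascade suppression**: a span already flagged `GEN002` is not
  re-flagged by downstream type rules — one underline per root cause.
- **Event assignments** are runtime actions, not initializations; they
  never trigger the override warnings, but they do make their target
  non-constant on the SBML side.

Output is deterministic: ordered by (line, column, rule id), one diagnostic
per (rule, symbol, span), identical across repeated runs.

## SBML translation

Targets SBML Level 3 Version 1 core, serialized with lxml. Mapping:
species (compartment membership, `initialConcentration` from literal
initializations, `boundaryCondition` from `$`/`const`), compartments (an
implicit `default_compartment` of size 1 appears when species are declared
without one), parameters (non-constant when governed by a rule or event
assignment), reactions (reversibility from the arrow, `speciesReference`
stoichiometries, kinetic-law math as content MathML, law species that are
not participants listed as modifiers), initial assignments for non-literal
`=` initializations, assignment/rate rules, events (persistent triggers,
initial value true), function definitions as MathML lambdas, display names
as `name` attributes, and annotation statements as MIRIAM CV terms
(`bqbiol:is` for `identity`, the other qualifiers mapped by name) attached
via `metaid`. Conversion is refused — with the blocking diagnostics — while
the document carries error-severity diagnostics; warnings do not block.

Comments have no SBML representation; they are dropped and itemized
per-comment in the conversion report rather than smuggled into `<notes>`.
Unit declarations are parsed and carried on the Antimony side only.
Modular-model instantiations are flattened into the single core model,
renaming inner symbols with the *instance* name as prefix (instance rather
than model name, so two instantiations of the same model cannot collide)
and substituting actual arguments for formals. Reading SBML accepts L2 and
L3 core; elements from non-core packages (FBC, comp, distrib, ...) are
skipped with a warning naming the construct. Conversion is deterministic:
identical input text yields byte-identical XML.

Semantic equivalence of two Antimony documents compares the *flattened
model*, not the text: species/parameter/compartment sets with initial
values, reaction participants with stoichiometries and reversibility,
kinetic-law expression trees normalized for commutativity (operands of `+`
and `*` sorted), display names and (element, qualifier, URI) annotation
triples. Statement order is irrelevant; the species-without-compartment vs
explicit-default-compartment phrasings compare equal. Pair synchronization
(`sync_pair`) propagates an edit on either side of an (`.ant`, `.xml`)
couple to the other, is a checksummed no-op for unchanged text, and leaves
the partner untouched when conversion is refused.

## Editor services

Hover, completion, go-to-definition, token classification and annotation
coverage are pure functions of (document text, 0-based position), so any
editor adapter or script can call them statelessly. The completion context
is derived solely from the tokens left of the cursor: an arrow seen means
product (or kinetic law once a `;` follows), an `=`/`:=` means
assignment right-hand side, a `+`/`$`/trailing label colon means reactant,
otherwise general. Reactant/product contexts admit only species; rate-law
and assignment contexts admit species, parameters, compartments and
functions. Ordering is type priority for the context, then lexicographic;
prefix matching is case-sensitive and exact (no fuzzy ranking — it would be
underdetermined). The partially typed word itself is excluded from its own
suggestions. Hover output is a stable plain-text `key: value` block;
token classification covers every non-whitespace token exactly once, with
`string` and `modelName` classes added for tokens the classic highlight
set has no name for.

## Rate-law templates

The registry ships irreversible mass action (`k*∏ reactant^stoich`, any
arity ≥ 1), reversible mass action (`kf*∏R − kr*∏P`), irreversible
Michaelis–Menten (`Vmax*S/(Km + S)`, uni-reactant), a simplified
reversible Michaelis–Menten with a single half-saturation constant
(`(Vf*S − Vr*P)/(Km + S + P)` — chosen so each constant appears once and
can be a single `__` slot; the full Haldane-constrained form is out of
scope), and a Hill expression (`Vmax*S^h/(K^h + S^h)`). Placeholders render
literally as `__`; binding maps short role names (`k`, `kf`, `kr`, `Vmax`,
`Vf`, `Vr`, `Km`, `K`, `h`) to identifiers, substituting every occurrence
of the role. A document containing `__` is a draft (reported by
`pending_placeholders`), not an error. When all participating species share
one declared compartment the law gains that compartment as volume factor
(`cell*k*S`); with mixed or absent compartments no factor is guessed.
Arity-qualified display names ("Irreversible Mass-Action Bi-Uni") are
derived from the reaction's reactant/product counts.

## Annotation

Knowledge sources are ranked by type appropriateness — ChEBI and UniProt
for species, Rhea and GO for reactions (GO also for whole-model processes)
— with the full registry always returned so the user can override. URIs
follow the identifiers.org pattern; the qualifier defaults to the
identity-style biological qualifier (the safest MIRIAM default) unless the
caller overrides. Queries run through a pluggable backend: the offline
fixture backend (canned JSON responses) serves all tests; a thin REST
backend (EBI OLS, Rhea, UniProt) exists for live use and is exercised only
manually. Backend failure raises a retriable `QueryError`, distinct from a
legitimately empty hit list. Applied annotations append one statement at
the bottom of the element's enclosing model block and are idempotent per
(element, URI) pair.

## Synthetic data

Two generators provide all test inputs; no data files ship with the
package.

`generate_fixture(FixtureSpec(n_species, n_reactions, faults, seed))`
builds a seeded mass-action network: every species initialized with an
integer amount in [1, 20], uni/bi reactions drawn uniformly over the
species pool with rate constants in [0.1, 5.0], roughly one reaction in
three reversible. A clean fixture yields zero diagnostics by construction.
Each requested fault id appends a minimal statement group that violates
exactly that rule; the manifest records the expected (rule, symbol) pairs
and any unavoidable cascades (e.g. the uninitialized-species injection for
`REA001` necessarily also fires `SPC001` for the species it leaves
uninitialized). The same spec always produces byte-identical text. Default
sweep/round-trip sizes (3–4 species, 2–3 reactions, 100 seeds) keep each
property run in fractions of a second while exercising every statement
path; these networks emulate the *structure* of curated models (typed
symbols, mass-action laws, compartments) but not their biological realism
— curated-model features such as SBO terms, nested comp hierarchies, units
and algebraic rules are exactly the constructs the translator either
carries verbatim or reports as unsupported, so green tests here certify
the language layer, not curation quality.

`synthetic_chemotaxis_model()` is a stand-in for the bacterial chemotaxis
phosphorelay (receptor-complex assembly from W/AA/TT subunits,
complex phosphorylation, phosphotransfer to the response regulator Y
through Y → Yp → Ypp): 32 mass-action reactions in a `cell` compartment of
which exactly 7 have Y as reactant and Yp as product, matching the
published network's headline structure. It is *synthetic* — constructed to
that shape, not downloaded — and serves as the offline payload for the
recorded BioModels client; the live REST client is code-complete but needs
network access.

## Numerical and degenerate-input choices

- Stoichiometries are floats; integral values print without a decimal
  point, so `2 H2` survives round trips unchanged.
- Expression canonicalization sorts commutative operands by their rendered
  string — a tie-break that is total, deterministic and independent of
  input order.
- MathML `cn` values keep integer form when the source literal was
  integral; e-notation and rational `cn` types are folded to floats on
  read.
- Empty documents are valid everywhere: parsing yields an empty document
  node, conversion an empty SBML model, the symbol table a single empty
  `__main` scope.
- Position queries past end-of-file return "nothing" rather than erroring.

## Known limitations

- No CellML output; no SBML packages (FBC, distrib, comp) — package
  elements are detected and skipped with a warning on read, never emitted.
- No unit dimensional analysis: unit declarations parse and render but do
  not reach SBML `unitDefinition`s.
- Algebraic rules in SBML input are skipped with a warning (Antimony has
  no direct equivalent in the supported subset).
- A valueless SBML parameter is given value 0 with a warning on conversion
  to Antimony, since the Antimony side would otherwise be unconvertible
  back (a parameter without a value is an error-severity diagnostic).
- The reversible Michaelis–Menten template is the simplified
  single-`Km` form, not the Haldane-constrained mechanism.
- `semantic_equivalent` compares flattened models; it will call two
  documents equal that differ only in modular structure.
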