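# antimonykit

A model-aware language toolkit for [Antimony](https://tellurium.readthedocs.io/en/latest/antimony.html),
the human-readable textual representation of SBML reaction-network models.

Text editors treat a biochemical model as characters; a *model-aware* tool
knows that `S1` is a species, `k1` a parameter and `J0: S1 => S2; k1*S1` an
irreversible reaction with a mass-action law. `antimonykit` provides that
awareness as a library plus a small CLI, for anyone building editor
integrations, model-curation pipelines or QA checks around Antimony/SBML
models:

- **Build** — context-dependent name completion (a parameter is suggested
  inside a rate law but never as a reactant), file imports, kinetic rate-law
  templates (mass action, Michaelis–Menten, Hill) instantiated for a
  reaction with `__` placeholders for the constants, and ontology
  annotation (ChEBI, Rhea, GO, UniProt) written as identifiers.org
  statements.
- **Analyze** — a scoped symbol table typing every identifier, a 23-rule
  static diagnostic catalog (errors block simulation, e.g. a parameter with
  no value; warnings flag questionable practice, e.g. silently overriding a
  value), hover content, go-to-definition, syntax-token classification and
  annotation-coverage reports.
- **Translate** — bidirectional Antimony ↔ SBML Level 3 Version 1 (core)
  conversion with an explicit lossiness report (comments cannot be
  represented in SBML) and checksummed synchronization of a paired
  (`.ant`, `.xml`) file couple.

## Worked example

```python
from antimonykit import parse
from antimonykit.ratelaws import get_template, instantiate_rate_law
from antimonykit.sbml import antimony_to_sbml

rx = parse("Yp+TTWWAAp=>Ypp+TTWWAA").ast.children[0]
law = instantiate_rate_law(get_template("mass_action_irrev"), rx)
print(law.expression_text)                       # __*Yp*TTWWAAp
print(law.bind({"k": "phosphotransfer_r12_k1"}))  # phosphotransfer_r12_k1*Yp*TTWWAAp
```

The `__` token marks a constant the modeler still has to supply — here the
mass-action rate constant, bound in the second line. Linting a model with an
unresolved parameter shows the severity split:

```
$ antkit fixture --species 3 --reactions 2 --fault PRM001 --seed 1 > bad.ant
$ antkit lint bad.ant
10:18: error [PRM001] parameter 'k_missing' has no initial value
```

(exit status 1: an error-severity diagnostic means the model cannot be
simulated). Converting a clean model emits SBML L3V1 and reports what was
lost:

```
$ antkit convert model.ant --to sbml -o model.xml
WARNING lossy: comment dropped: // just a note
```

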