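# pathwayqc

Rule-based quality control and complementation for manually curated
biological pathway models.

Curated pathway databases are built by hand from the literature, and even
careful curators misassign ontology concepts and terms: a kinase wired as
a second substrate instead of an activator, a receptor-complex binding
labelled as a dimerization, a transcription product missing its location,
a modified protein without its feature annotation. Such mistakes are
invisible to schema-level ontology validation — the instance data is
syntactically fine — yet they corrupt the biology and block dynamic
simulation. `pathwayqc` is for curators and pathway-database maintainers
who want these mistakes caught mechanically, and models upgraded to
simulation readiness, before integration, exchange or simulation.

## The model and the rules

A pathway is a bipartite graph in the Petri-net tradition: entities
(places) are typed molecules annotated with cellular location (`CC_*`),
modification states (`FT_*`) and external references; processes
(transitions) carry a biological-event term (`ME_*`); role-typed
connectors (arcs) — substrate, inhibitor, activator, product — join one
process to one entity, with a stoichiometric coefficient on the arc.

A registry of 40 event-condition-action rules checks three criteria:

1. **Structural** (1 rule): each (process, entity) pair admits at most one
   connector — an entity takes exactly one role in a process.
2. **Biological** (36 rules, one per rule-covered event, in five groups):
   declarative constraints over participant cardinality, entity types,
   property values and cross-participant property relationships. For
   example, dimerization takes exactly one substrate with coefficient 2
   and produces one `Complex` (oligomerization: coefficients 3–20;
   polymerization: ≥ 21); phosphorylation's product must carry
   `FT_Phosphorylated` and share the substrate's external reference;
   internalization moves one molecule from the cell surface
   to the cytosol. Violations are reported in a categorized warning
   taxonomy (wrong/missing cardinality, type, location, feature,
   stoichiometry, reference, ...).
3. **Simulation readiness** (3 rules, mutating): every species never
   produced gets an unknown-production source (complexes: a binding
   process over their components) and every degradable species without a
   sink gets an unknown-degradation process — the protein-turnover
   skeleton a token simulator needs.

The 36 event constraints ship as data
(`src/pathwayqc/data/constraints.json`), each tagged with provenance, and
can be overridden per run. Details, defaults and design choices are in
[docs/methods.md](docs/methods.md); the JSON model dialect is documented
in [docs/model_format.md](docs/model_format.md).

## Worked example

A classic curation mistake: Ras{active} activates Raf1, but the curator
wired the active Ras as a second substrate of the unknown-activation
process instead of as an activator.

```python
import pathwayqc as pq

case1, case1_fixed, case2, case2_fixed = pq.make_case_models()
report = pq.evaluate(case1)
print(report.to_text())
```

```
model case1: 1 warning(s)
process act1 [ME_UnknownActivation]:
  WRONG_CARDINALITY_INPUTPROCESS: ME_UnknownActivation requires exactly 1 inputprocess entities, found 2
```

An activation consumes exactly one substrate, so two substrate connectors
flag the process. Re-wiring Ras{active} through an activator connector
(`case1_fixed`) makes the report empty. The second bundled case is a
binding of two *different* molecules mislabelled `ME_Dimerization`;
relabelling the event to `ME_Binding` clears its cardinality warning.

Complementation on a minimal chain `A → P → B` (both proteins):

```python
new_model, delta = pq.complement_model(model)
print(delta.counts)   # {'productions': 1, 'bindings': 0, 'degradations': 2}
sorted(new_model.processes)
# ['A__unknown_degradation', 'A__unknown_production', 'B__unknown_degradation', 'P']
```

`A` is never produced, so it gains a source; both proteins gain sinks;
`B` is already produced by `P`. A second pass adds nothing.

The same operations are available from the shell:

```sh
pathwayqc validate model.json --format json     # exit 0 clean / 1 warnings / 2 errors
pathwayqc complement model.json -o ready.json
pathwayqc rules list --criterion 2 --group 3
pathwayqc fixtures --seed 7 --processes 20 -o fixture.json
```

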