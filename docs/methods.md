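# Methods

## The model

A curated pathway is represented as a bipartite graph in the Petri-net
tradition: **entities** (places) are typed molecular species, **processes**
(transitions) are biological events, and **connectors** (arcs) join exactly
one process to exactly one entity in one of four roles — substrate
(`InputProcessBiological`), inhibitor (`InputInhibitorBiological`),
activator (`InputAssociationBiological`), product
(`OutputProcessBiological`). The first three form the input role family.
Entities carry a class (`Protein`, `Dna`, `mRNA`, `SmallMolecule`,
`Complex`, or the undeclared root `Entity`), an optional cellular location
(`CC_*`), modification states (`FT_*`), external database references
(`db:accession`), and, for complexes, a component list. Processes carry a
biological-event term (`ME_*`). The stoichiometric coefficient lives on
the connector, not the entity: one molecule can enter different processes
with different multiplicities, and every rule that reads a coefficient
means "the coefficient of that entity *in that process*".

Curation errors this tool targets are misassignments and misuse of the
controlled vocabulary: the wrong connector role, the wrong or missing
entity class, a wrong or absent location, a forgotten modification state
or external reference, and coefficients inconsistent with the event.

## The rule system

Validation is organised as event-condition-action rules over the graph;
the registry holds exactly 40.

**Criterion 1 — structural correctness (1 rule).** One entity may
participate in a process with only one role, so each (process, entity)
pair admits at most one connector; five configurations are valid (no
connection, or one connector in one of the four roles). Two or more
connectors on a pair yields one `INVALID_CONNECTION` warning listing every
connector of the pair as a fix candidate. The tool never auto-repairs
this: picking the right connector requires understanding the interaction,
so the action is a report with machine-readable candidates.

**Criterion 2 — biological correctness (36 rules).** Each rule binds to
one event term (exact string match, no term hierarchy) and combines four
clause kinds evaluated in fixed order: cardinality, type, property,
property-relationship. The 36 events split into five template groups —
see `pathwayqc/data/constraints.json`, which is the actual artifact: the
rules are data, not code.

- *Group 1 (11 events)* — cardinality + type. E.g. DNA binding requires at
  least two substrates, at least one of class `Dna`, and `Complex`
  products.
- *Group 2 (15 events)* — post-translational modifications: exactly one
  substrate, a product carrying the feature type mapped from the event
  (the event→feature map is total on group 2 but not injective —
  phosphorylation and autophosphorylation both map to
  `FT_Phosphorylated`), and a shared external reference between substrate
  and product, because the product is a modified form of the same
  molecule. Self-events (autophosphorylation, and autocleavage in group 1)
  occur without an enzyme, expressed as "exactly one input entity in
  total"; plain modifications permit extra activator/inhibitor inputs.
- *Group 3 (3 events)* — the chemical union of identical molecules: one
  substrate whose coefficient is exactly 2 (dimerization), 3–20
  (oligomerization) or ≥ 21 (polymerization), and one `Complex` product.
- *Group 4 (3 events)* — location-constrained transport: internalization
  (extracellular/plasma membrane → cytosol), nuclear export (nucleoplasm →
  cytoplasm), translocation (both locations present and *different*), each
  with a shared-reference requirement.
- *Group 5 (4 events)* — type + location on products: transcription yields
  one nucleoplasmic `mRNA`, translation one cytoplasmic `Protein` from an
  mRNA-bearing input, etc.

**Criterion 3 — simulation readiness (3 rules).** Condition-action rules
whose action mutates the model; see Complementation below.

### Warning semantics and numerical choices

- One warning per violated clause per process; multiple offending entities
  of one clause are listed in a single warning, not fanned out. A process
  can therefore yield several warnings of different categories (and a
  location clause can yield both a wrong-value and a missing-value
  warning when one participant is mislocated and another is unplaced).
- Wrong vs missing are distinct categories throughout (`WRONG_TYPE` vs
  `MISSING_TYPE`, etc.): a type clause reports `MISSING_TYPE` when every
  offender has the undeclared root class and `WRONG_TYPE` otherwise.
- **Suppression**: a role required by a lower cardinality bound but empty
  is reported once (`MISSING_INPUTPROCESS` / `MISSING_OUTPUT`, or the
  wrong-cardinality category for the input family, which has no printed
  missing variant) and its dependent type/property/relationship clauses
  are skipped — properties of an absent entity cannot be judged, and
  reporting them would double-count one mistake. A cardinality violation
  with survivors (two substrates where one is required) does *not*
  suppress: the present entities are still checked.
- Reference comparison is case-insensitive on both database and accession;
  entities with multiple references are "the same molecule" if any
  reference is shared. When either side of a same-reference clause has no
  references at all, the clause reports `MISSING_UNIFICATIONXREF` and the
  comparison is not attempted; a genuine mismatch (both sides annotated,
  nothing shared) is the distinct `WRONG_UNIFICATIONXREF`.
- Location comparison is exact term equality; no location hierarchy is
  modelled.
- Coefficients are integers ≥ 1; all rule thresholds are integral.
- Reports are deterministic: warnings sort by (process id, rule id,
  category, entity ids), serialization sorts records and keys, and the
  per-event TSV summary is an exact marginal of the warning list.
- Events with no rule (8 terms in the default survey vocabulary, e.g.
  cleavage and unknown interaction) are counted in an `uncovered_events`
  side channel, never warned: absence of a rule is deliberate for events
  with no distinguishing characteristics.
- `evaluate()` is strictly read-only. When criterion 3 is requested it
  reports the number of species each complementation rule *would* touch
  in the `complementation_needed` side channel; the warning taxonomy is
  reserved for criteria 1–2.

### Provenance of the constraint table

Seven constraints transcribe printed rules (`provenance: "paper"`): DNA
binding, acetylation, autophosphorylation, the three stoichiometry rules,
internalization, transcription. The remainder are synthesized defaults
built from the group templates and the documented reasons per event
(`provenance: "synthesized"`); they are deliberately config-overridable
(`--constraint-table`), and user-supplied tables load with
`provenance: "user"`. The feature map entries for unknown
activation/inactivation (`FT_Active`/`FT_Inactive`) and for the
de-modification events (`FT_Dephosphorylated`, `FT_Deubiquitinated`) are
documented guesses in the same spirit, not asserted vocabulary facts.
Strict loading enforces the registry cardinalities: 36 events in groups of
sizes (11, 15, 3, 3, 4), feature map total on group 2.

## Complementation

For token-based simulation every species needs a source and a sink
(protein turnover). Detection runs entirely on the pre-mutation state
(simultaneous semantics), then the delta is applied:

- a **starting entity** — non-complex, all of its connectors input-role —
  gains an `ME_UnknownProduction` process producing it. Isolated entities
  qualify vacuously: the universal condition is literally true, and a
  species with no source cannot be simulated;
- a **starting complex** gains an `ME_Binding` process with its recorded
  components as substrates; a complex without recorded components falls
  back to unknown production (with a provenance note) rather than
  erroring, so complementation is total;
- a **degrading entity** — any Protein, Complex, mRNA or SmallMolecule
  without a substrate connection to an `ME_UnknownDegradation` process —
  gains one. By default proteasome degradation does *not* exempt an entity
  (the condition names only unknown degradation); `include_proteasome=True`
  widens the exemption.

New node ids are deterministic (`<entity_id>__unknown_production` etc.) so
reruns produce identical diffs. One pass is complete: a second pass yields
an empty delta, nothing is ever removed or re-typed, and no kinetic
parameters or initial values are invented for added nodes — they carry
only structure and a note flagging them for downstream parameterization.

## Synthetic fixtures

The generator is the package's stand-in for real curated model corpora,
which are not redistributable. `make_clean_model` builds each process
*constructively from its constraint* (participants at the minimum
cardinalities, required classes, locations, features, coefficients, shared
references), so clean fixtures are warning-free by construction for all 36
events — that is itself a tested property. Event frequencies are drawn
with weights shaped like real curation load (binding and unknown
activation dominate); generation uses an integer-only RNG keyed by the
spec's seed, so fixtures are byte-identical across platforms.

`inject_violations` plants an exact number of defects per warning
category, each on a distinct process, and verifies every injection in
isolation (the process must yield exactly the one intended category) plus
the whole plan post hoc; unachievable plans fail loudly. The two worked
correction cases (an activation with the activating kinase miswired as a
second substrate; a receptor-complex binding mislabeled as dimerization)
set all non-focal annotations to satisfying values so the demonstrated
warning is isolated.

What the fixtures do **not** emulate: shared entities across processes
(each generated process gets fresh participants, so the graphs are star
forests rather than connected pathways), realistic display names,
cross-referenced complexes, or literature-derived annotation noise.
Passing tests therefore demonstrate the engine's clause semantics and
bookkeeping, not recall/precision on any real curated corpus.

## Problem sizes and verification

The test suite checks the engine against an independent brute-force
validator (plain loops over the raw constraint records, no shared clause
machinery) on 100 scrambled fixtures of ≥ 200 nodes each, sweeps
coefficients 1–40 exhaustively against set-membership oracles for the
group-3 boundaries, and runs constructive-soundness plus single-defect
mutation tests across all 36 events; property tests (hypothesis,
derandomised) cover serialization round-trips and complementation
idempotence/totality. These sizes keep the whole suite under a few
seconds while exercising every rule and category; the engine itself is
linear in connectors per evaluation.

## Known limitations

- No OWL/RDF parsing, reasoning, or SPARQL; the condition language is the
  small composable predicate set above, not a DL reasoner.
- No automatic repair of criterion-1/2 violations; fixing is a curator's
  decision and the tool only reports candidates.
- 29 of the 36 constraints are synthesized defaults; they are
  group-template-faithful but not transcriptions, and should be reviewed
  (and overridden via the table) before being treated as authoritative for
  a particular vocabulary release.
- External references are compared as opaque strings; no live database
  lookup or molecule-hierarchy resolution.
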