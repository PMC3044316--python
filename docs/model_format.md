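# Model JSON dialect

`pathwayqc`'s native serialization of a pathway model. One UTF-8 JSON
document per model, four top-level keys:

```json
{
  "model_id": "example",
  "entities":   [ ... ],
  "processes":  [ ... ],
  "connectors": [ ... ]
}
```

Writers emit records sorted by id, keys sorted, and all defaults written
explicitly (including `"stoichiometry": 1`), so saving the same model twice
is byte-identical.

## Entity records

```json
{
  "id": "raf1",
  "class": "Protein",
  "name": "Raf1",
  "cellComponent": "CC_Cytosol",
  "featureTypes": ["FT_Phosphorylated"],
  "xrefs": ["TRANSPATH:MO000012345"],
  "components": [],
  "annotations": {}
}
```

- `class` — one of `Entity`, `Protein`, `Dna`, `mRNA`, `SmallMolecule`,
  `Complex`. The concrete classes are subclasses of `Entity`; `Entity`
  itself marks an undeclared type. Default `Entity`.
- `cellComponent` — a `CC_*` location term or `null`.
- `featureTypes` — `FT_*` modification-state terms.
- `xrefs` — `db:accession` strings; external references identifying the
  underlying molecule (case-insensitive comparison).
- `components` — entity ids composing a complex; only entities of class
  `Complex` may list components, and composition must be acyclic.

## Process records

```json
{"id": "p1", "event": "ME_Phosphorylation", "name": "...", "annotations": {}}
```

`event` (an `ME_*` biological-event term) is mandatory; a process without
it is a load error. Unknown vocabulary terms load fine and are reported as
notices, never errors.

## Connector records

```json
{"id": "c1", "role": "InputProcessBiological", "process": "p1",
 "entity": "raf1", "stoichiometry": 1, "annotations": {}}
```

- `role` — `InputProcessBiological` (substrate), `InputInhibitorBiological`
  (inhibitor), `InputAssociationBiological` (activator), or
  `OutputProcessBiological` (product).
- `process` / `entity` — ids that must resolve; a connector always joins
  exactly one process and one entity (bipartiteness by construction).
- `stoichiometry` — positive integer coefficient, default 1.

## Strict vs lax loading

In lax mode (default), unknown record keys are preserved in the record's
`annotations` — this is where simulation-only attributes (initial values,
kinetics) survive a round trip. In strict mode (`--strict` /
`strict=True`), unknown keys are errors.

All structural offenses (dangling references, duplicate ids, same-kind
endpoints, missing events, component cycles, non-positive coefficients)
are collected and reported together in one error.
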