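"""Model complementation: make a pathway simulation-ready.

In a token-based (Petri-net) simulation every species needs a source and a
sink, mirroring protein turnover: species are synthesized within the cell
and gradually broken down again. Three condition-action rules rewrite the
model accordingly:

* **starting entity** — a non-complex entity never produced by any process
  (all its connectors are input-role; an isolated entity qualifies
  vacuously) gets an ``ME_UnknownProduction`` pre-process producing it;
* **starting complex** — a complex never produced gets an ``ME_Binding``
  process producing it, with the complex's recorded components as
  substrates (a complex without recorded components falls back to unknown
  production, so complementation is total);
* **degrading entity** — every Protein, Complex, mRNA or SmallMolecule
  without a degradation process gets an ``ME_UnknownDegradation`` process
  consuming it.

Detection runs on the input model before any mutation (simultaneous
semantics), so one pass is enough and a second pass is a no-op. Added
nodes carry only structure — no kinetics or initial values are invented;
they are flagged for downstream parameterization via a provenance note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .model import Connector, ConnectorRole, PathwayModel, Process
from .vocab import (
    ME_BINDING,
    ME_UNKNOWN_DEGRADATION,
    ME_UNKNOWN_PRODUCTION,
    EntityClass,
)

__all__ = [
    "ModelDelta",
    "find_starting_entities",
    "find_starting_complexes",
    "find_degrading_entities",
    "complement_model",
]

#: classes subject to the degradation rule
DEGRADABLE_CLASSES = frozenset({
    EntityClass.PROTEIN, EntityClass.COMPLEX,
    EntityClass.MRNA, EntityClass.SMALL_MOLECULE,
})


@dataclass
class ModelDelta:
    """The additions of one complementation pass; replayable and serializable."""

    added_processes: list[tuple[str, str, str]] = field(default_factory=list)
    #: (process_id, event_term, provenance_note)
    added_connectors: list[Connector] = field(default_factory=list)

    def is_empty(self) -> bool:
        return not self.added_processes and not self.added_connectors

    @property
    def counts(self) -> dict[str, int]:
        out = {"productions": 0, "bindings": 0, "degradations": 0}
        for _, event, _ in self.added_processes:
            if event == ME_UNKNOWN_PRODUCTION:
                out["productions"] += 1
            elif event == ME_BINDING:
                out["bindings"] += 1
            elif event == ME_UNKNOWN_DEGRADATION:
                out["degradations"] += 1
        return out

    def apply(self, model: PathwayModel) -> PathwayModel:
        out = model.copy()
        for pid, event, note in self.added_processes:
            out.add_process(Process(
                id=pid, biological_event=event,
                annotations={"complemented": note},
            ))
        for c in self.added_connectors:
            out.add_connector(Connector(
                id=c.id, role=c.role, process_id=c.process_id,
                entity_id=c.entity_id, stoichiometry=c.stoichiometry,
                annotations=dict(c.annotations),
            ))
        out.check()
        return out

    def to_json(self) -> str:
        doc = {
            "added_processes": [
                {"id": pid, "event": event, "note": note}
                for pid, event, note in self.added_processes
            ],
            "added_connectors": [
                {"id": c.id, "role": c.role.value, "process": c.process_id,
                 "entity": c.entity_id, "stoichiometry": c.stoichiometry}
                for c in self.added_connectors
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "ModelDelta":
        doc = json.loads(text)
        delta = cls()
        for rec in doc.get("added_processes", []):
            delta.added_processes.append(
                (rec["id"], rec["event"], rec.get("note", ""))
            )
        for rec in doc.get("added_connectors", []):
            delta.added_connectors.append(Connector(
                id=rec["id"], role=ConnectorRole(rec["role"]),
                process_id=rec["process"], entity_id=rec["entity"],
                stoichiometry=rec.get("stoichiometry", 1),
            ))
        return delta


def find_starting_entities(model: PathwayModel) -> list[str]:
    """Non-complex entities connected to processes only via input-role
    connectors (isolated entities qualify vacuously); sorted by id."""
    out = []
    for eid in sorted(model.entities):
        e = model.entities[eid]
        if e.entity_class is EntityClass.COMPLEX:
            continue
        if all(c.role.is_input for c in model.entity_connectors(eid)):
            out.append(eid)
    return out


def find_starting_complexes(model: PathwayModel) -> list[str]:
    """Starting entities of class Complex; sorted by id."""
    out = []
    for eid in sorted(model.entities):
        e = model.entities[eid]
        if e.entity_class is not EntityClass.COMPLEX:
            continue
        if all(c.role.is_input for c in model.entity_connectors(eid)):
            out.append(eid)
    return out


def find_degrading_entities(
    model: PathwayModel, include_proteasome: bool = False
) -> list[str]:
    """Protein/Complex/mRNA/SmallMolecule entities lacking a degradation
    process (i.e. no substrate connection to an ME_UnknownDegradation
    process; with ``include_proteasome``, ME_ProteasomeDegradation also
    counts as degradation); sorted by id."""
    degraded: set[str] = set()
    degradation_events = {ME_UNKNOWN_DEGRADATION}
    if include_proteasome:
        degradation_events.add("ME_ProteasomeDegradation")
    for c in model.connectors.values():
        if c.role is not ConnectorRole.SUBSTRATE:
            continue
        p = model.processes.get(c.process_id)
        if p is not None and p.biological_event in degradation_events:
            degraded.add(c.entity_id)
    return [
        eid for eid in sorted(model.entities)
        if model.entities[eid].entity_class in DEGRADABLE_CLASSES
        and eid not in degraded
    ]


def complement_model(
    model: PathwayModel, include_proteasome: bool = False
) -> tuple[PathwayModel, ModelDelta]:
    """Apply all three complementation rules and return (new model, delta).

    The input model is untouched; new node ids are derived from the target
    entity id plus a rule tag, so reruns produce identical diffs.
    """
    delta = ModelDelta()

    for eid in find_starting_entities(model):
        pid = f"{eid}__unknown_production"
        delta.added_processes.append(
            (pid, ME_UNKNOWN_PRODUCTION, f"source for starting entity {eid}")
        )
        delta.added_connectors.append(Connector(
            id=f"{pid}_out", role=ConnectorRole.PRODUCT,
            process_id=pid, entity_id=eid,
        ))

    for eid in find_starting_complexes(model):
        components = model.entities[eid].component_ids
        if components:
            pid = f"{eid}__binding"
            delta.added_processes.append(
                (pid, ME_BINDING, f"binding producing starting complex {eid}")
            )
            delta.added_connectors.append(Connector(
                id=f"{pid}_out", role=ConnectorRole.PRODUCT,
                process_id=pid, entity_id=eid,
            ))
            for cid in components:
                delta.added_connectors.append(Connector(
                    id=f"{pid}_in_{cid}", role=ConnectorRole.SUBSTRATE,
                    process_id=pid, entity_id=cid,
                ))
        else:
            # composition unknown: a binding process cannot be synthesized,
            # fall back to unknown production so every species gets a source
            pid = f"{eid}__unknown_production"
            delta.added_processes.append((
                pid, ME_UNKNOWN_PRODUCTION,
                f"source for starting complex {eid} (components unrecorded)",
            ))
            delta.added_connectors.append(Connector(
                id=f"{pid}_out", role=ConnectorRole.PRODUCT,
                process_id=pid, entity_id=eid,
            ))

    for eid in find_degrading_entities(model, include_proteasome):
        pid = f"{eid}__unknown_degradation"
        delta.added_processes.append(
            (pid, ME_UNKNOWN_DEGRADATION, f"sink for entity {eid}")
        )
        delta.added_connectors.append(Connector(
            id=f"{pid}_in", role=ConnectorRole.SUBSTRATE,
            process_id=pid, entity_id=eid,
        ))

    return delta.apply(model), delta
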