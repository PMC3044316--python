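"""Bipartite pathway graph: entities, processes and role-typed connectors.

A pathway model is a bipartite graph in the Petri-net tradition: entities
(places) hold molecular species, processes (transitions) are biological
events, and connectors (arcs) join exactly one process to exactly one
entity with one of four roles:

* ``InputProcessBiological`` — substrate, consumed by the process;
* ``InputInhibitorBiological`` — inhibitor;
* ``InputAssociationBiological`` — activator;
* ``OutputProcessBiological`` — product.

The first three form the *input* role family. The native serialization is a
small JSON dialect (see ``docs/model_format.md``); GraphML export is
provided for visual inspection.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Iterator

from .vocab import CC, EntityClass, FT, ME, is_a, namespace_of

__all__ = [
    "Xref",
    "Entity",
    "Process",
    "ConnectorRole",
    "Connector",
    "PathwayModel",
    "ModelError",
    "LookupIdError",
    "load_model",
    "loads_model",
    "save_model",
    "dumps_model",
    "to_graphml",
]


class ModelError(ValueError):
    """Structural problem in a model document: every offense is listed."""

    def __init__(self, offenses: list[str]):
        self.offenses = list(offenses)
        super().__init__("invalid model: " + "; ".join(self.offenses))


class LookupIdError(KeyError):
    """An id that should resolve within the model does not."""


@dataclass(frozen=True, order=True)
class Xref:
    """External database cross-reference identifying a molecule.

    Two xrefs denote the same record iff database and accession both match
    after case normalization.
    """

    db: str
    accession: str

    def same_as(self, other: "Xref") -> bool:
        return (
            self.db.casefold() == other.db.casefold()
            and self.accession.casefold() == other.accession.casefold()
        )

    @classmethod
    def parse(cls, text: str) -> "Xref":
        db, sep, acc = text.partition(":")
        if not sep or not db or not acc:
            raise ValueError(f"xref must be 'db:accession', got {text!r}")
        return cls(db, acc)

    def __str__(self) -> str:
        return f"{self.db}:{self.accession}"


def xrefs_share(a: Iterable[Xref], b: Iterable[Xref]) -> bool:
    """True if any xref in *a* is same-as any xref in *b*."""
    bn = {(x.db.casefold(), x.accession.casefold()) for x in b}
    return any((x.db.casefold(), x.accession.casefold()) in bn for x in a)


@dataclass
class Entity:
    """A molecular species (Petri-net place).

    ``component_ids`` records complex composition and is non-empty only for
    entities of class Complex. ``annotations`` preserves simulation-only
    attributes opaquely; no rule reads them.
    """

    id: str
    entity_class: EntityClass = EntityClass.ENTITY
    display_name: str = ""
    cell_component: str | None = None
    feature_types: frozenset[str] = frozenset()
    unification_xrefs: frozenset[Xref] = frozenset()
    component_ids: tuple[str, ...] = ()
    annotations: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.feature_types = frozenset(self.feature_types)
        self.unification_xrefs = frozenset(self.unification_xrefs)
        self.component_ids = tuple(self.component_ids)


@dataclass
class Process:
    """A biological event occurrence (Petri-net transition)."""

    id: str
    biological_event: str
    display_name: str = ""
    annotations: dict[str, Any] = field(default_factory=dict)


class ConnectorRole(str, enum.Enum):
    SUBSTRATE = "InputProcessBiological"
    INHIBITOR = "InputInhibitorBiological"
    ACTIVATOR = "InputAssociationBiological"
    PRODUCT = "OutputProcessBiological"

    def __str__(self) -> str:
        return self.value

    @property
    def is_input(self) -> bool:
        return self is not ConnectorRole.PRODUCT


#: the three roles through which an entity feeds a process
INPUT_ROLES = (
    ConnectorRole.SUBSTRATE,
    ConnectorRole.INHIBITOR,
    ConnectorRole.ACTIVATOR,
)


@dataclass
class Connector:
    """Arc joining one process and one entity with a single role.

    The stoichiometric coefficient is the multiplicity with which the
    entity enters this process (2 for a homodimerization substrate, etc.);
    it lives on the connector because one entity may enter different
    processes with different coefficients.
    """

    id: str
    role: ConnectorRole
    process_id: str
    entity_id: str
    stoichiometry: int = 1
    annotations: dict[str, Any] = field(default_factory=dict)


@dataclass
class PathwayModel:
    """A whole curated pathway: keyed collections of the three node kinds."""

    model_id: str = "model"
    entities: dict[str, Entity] = field(default_factory=dict)
    processes: dict[str, Process] = field(default_factory=dict)
    connectors: dict[str, Connector] = field(default_factory=dict)

    # -- construction helpers ------------------------------------------------

    def add_entity(self, entity: Entity) -> Entity:
        if entity.id in self.entities:
            raise ModelError([f"duplicate entity id {entity.id!r}"])
        self.entities[entity.id] = entity
        return entity

    def add_process(self, process: Process) -> Process:
        if process.id in self.processes:
            raise ModelError([f"duplicate process id {process.id!r}"])
        self.processes[process.id] = process
        return process

    def add_connector(self, connector: Connector) -> Connector:
        if connector.id in self.connectors:
            raise ModelError([f"duplicate connector id {connector.id!r}"])
        self.connectors[connector.id] = connector
        return connector

    def copy(self) -> "PathwayModel":
        return PathwayModel(
            model_id=self.model_id,
            entities={k: replace(v, annotations=dict(v.annotations)) for k, v in self.entities.items()},
            processes={k: replace(v, annotations=dict(v.annotations)) for k, v in self.processes.items()},
            connectors={k: replace(v, annotations=dict(v.annotations)) for k, v in self.connectors.items()},
        )

    # -- invariants ----------------------------------------------------------

    def check(self) -> None:
        """Raise ModelError listing every violated structural invariant."""
        offenses: list[str] = []
        for c in self.connectors.values():
            if c.process_id not in self.processes:
                offenses.append(
                    f"connector {c.id!r} references missing process {c.process_id!r}"
                )
            if c.entity_id not in self.entities:
                offenses.append(
                    f"connector {c.id!r} references missing entity {c.entity_id!r}"
                )
            if c.process_id in self.entities:
                offenses.append(
                    f"connector {c.id!r}: process endpoint {c.process_id!r} is an entity"
                )
            if c.entity_id in self.processes:
                offenses.append(
                    f"connector {c.id!r}: entity endpoint {c.entity_id!r} is a process"
                )
            if c.stoichiometry < 1:
                offenses.append(
                    f"connector {c.id!r}: stoichiometry {c.stoichiometry} < 1"
                )
        shared = set(self.entities) & set(self.processes)
        for node in sorted(shared):
            offenses.append(f"id {node!r} used for both an entity and a process")
        for p in self.processes.values():
            if not p.biological_event:
                offenses.append(f"process {p.id!r} has no biological event")
        for e in self.entities.values():
            if e.component_ids and e.entity_class is not EntityClass.COMPLEX:
                offenses.append(
                    f"entity {e.id!r} has components but class {e.entity_class}"
                )
            for cid in e.component_ids:
                if cid not in self.entities:
                    offenses.append(
                        f"entity {e.id!r} lists missing component {cid!r}"
                    )
        offenses.extend(self._component_cycles())
        if offenses:
            raise ModelError(offenses)

    def _component_cycles(self) -> list[str]:
        # no entity may be its own transitive component
        offenses = []
        for start in self.entities:
            seen, stack = set(), [start]
            while stack:
                cur = stack.pop()
                ent = self.entities.get(cur)
                if ent is None:
                    continue
                for cid in ent.component_ids:
                    if cid == start:
                        offenses.append(
                            f"entity {start!r} is its own transitive component"
                        )
                        stack = []
                        break
                    if cid not in seen:
                        seen.add(cid)
                        stack.append(cid)
        return offenses

    def vocabulary_notices(self) -> list[str]:
        """Unknown ME/FT/CC terms (open-world: notices, not errors)."""
        from . import vocab

        notices = []
        for p in sorted(self.processes.values(), key=lambda p: p.id):
            if namespace_of(p.biological_event) != ME:
                notices.append(
                    f"process {p.id!r}: event {p.biological_event!r} is not an ME_ term"
                )
            elif p.biological_event not in vocab.KNOWN_ME_TERMS:
                notices.append(
                    f"process {p.id!r}: unknown event term {p.biological_event!r}"
                )
        for e in sorted(self.entities.values(), key=lambda e: e.id):
            if e.cell_component is not None and namespace_of(e.cell_component) != CC:
                notices.append(
                    f"entity {e.id!r}: location {e.cell_component!r} is not a CC_ term"
                )
            for ft in sorted(e.feature_types):
                if namespace_of(ft) != FT:
                    notices.append(
                        f"entity {e.id!r}: feature {ft!r} is not an FT_ term"
                    )
        return notices

    # -- graph-access predicates ---------------------------------------------

    def _require_process(self, process_id: str) -> Process:
        try:
            return self.processes[process_id]
        except KeyError:
            raise LookupIdError(f"unknown process id {process_id!r}") from None

    def _require_entity(self, entity_id: str) -> Entity:
        try:
            return self.entities[entity_id]
        except KeyError:
            raise LookupIdError(f"unknown entity id {entity_id!r}") from None

    def connectors_of(self, process_id: str) -> list[Connector]:
        self._require_process(process_id)
        return sorted(
            (c for c in self.connectors.values() if c.process_id == process_id),
            key=lambda c: c.id,
        )

    def connectors_between(self, process_id: str, entity_id: str) -> list[Connector]:
        """All connectors joining the given (process, entity) pair, any role.

        More than one connector on a pair is a structural violation (one
        entity may take only one role in a process); this accessor is what
        the valid-connection rule counts.
        """
        self._require_process(process_id)
        self._require_entity(entity_id)
        return sorted(
            (
                c
                for c in self.connectors.values()
                if c.process_id == process_id and c.entity_id == entity_id
            ),
            key=lambda c: c.id,
        )

    def _participants(
        self, process_id: str, roles: Iterable[ConnectorRole]
    ) -> list[tuple[Entity, Connector]]:
        roleset = set(roles)
        return [
            (self.entities[c.entity_id], c)
            for c in self.connectors_of(process_id)
            if c.role in roleset
        ]

    def has_input(self, process_id: str) -> list[tuple[Entity, Connector]]:
        """Entities joined via any of the three input roles (one pair per
        connector)."""
        return self._participants(process_id, INPUT_ROLES)

    def has_inputprocess(self, process_id: str) -> list[tuple[Entity, Connector]]:
        """Substrate entities (InputProcessBiological connectors only)."""
        return self._participants(process_id, (ConnectorRole.SUBSTRATE,))

    def has_output(self, process_id: str) -> list[tuple[Entity, Connector]]:
        """Product entities (OutputProcessBiological connectors only)."""
        return self._participants(process_id, (ConnectorRole.PRODUCT,))

    def entity_connectors(self, entity_id: str) -> list[Connector]:
        self._require_entity(entity_id)
        return sorted(
            (c for c in self.connectors.values() if c.entity_id == entity_id),
            key=lambda c: c.id,
        )

    def entity_is_a(self, entity_id: str, ancestor: EntityClass) -> bool:
        return is_a(self._require_entity(entity_id).entity_class, ancestor)

    def iter_processes(self) -> Iterator[Process]:
        for pid in sorted(self.processes):
            yield self.processes[pid]


# ---------------------------------------------------------------------------
# JSON serialization

_ENTITY_KEYS = {
    "id", "class", "name", "cellComponent", "featureTypes",
    "xrefs", "components", "annotations",
}
_PROCESS_KEYS = {"id", "event", "name", "annotations"}
_CONNECTOR_KEYS = {"id", "role", "process", "entity", "stoichiometry", "annotations"}


def _entity_to_json(e: Entity) -> dict[str, Any]:
    return {
        "id": e.id,
        "class": e.entity_class.value,
        "name": e.display_name,
        "cellComponent": e.cell_component,
        "featureTypes": sorted(e.feature_types),
        "xrefs": sorted(str(x) for x in e.unification_xrefs),
        "components": list(e.component_ids),
        "annotations": e.annotations,
    }


def _process_to_json(p: Process) -> dict[str, Any]:
    return {
        "id": p.id,
        "event": p.biological_event,
        "name": p.display_name,
        "annotations": p.annotations,
    }


def _connector_to_json(c: Connector) -> dict[str, Any]:
    return {
        "id": c.id,
        "role": c.role.value,
        "process": c.process_id,
        "entity": c.entity_id,
        "stoichiometry": c.stoichiometry,
        "annotations": c.annotations,
    }


def dumps_model(model: PathwayModel) -> str:
    """Serialize to the model-JSON dialect.

    Output is deterministic: records sorted by id, keys sorted, defaults
    (including stoichiometry 1) written out explicitly.
    """
    doc = {
        "model_id": model.model_id,
        "entities": [
            _entity_to_json(model.entities[k]) for k in sorted(model.entities)
        ],
        "processes": [
            _process_to_json(model.processes[k]) for k in sorted(model.processes)
        ],
        "connectors": [
            _connector_to_json(model.connectors[k]) for k in sorted(model.connectors)
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def save_model(model: PathwayModel, path_or_stream) -> None:
    text = dumps_model(model)
    if hasattr(path_or_stream, "write"):
        path_or_stream.write(text)
    else:
        with open(path_or_stream, "w", encoding="utf-8") as fh:
            fh.write(text)


def _want_mapping(obj: Any, what: str, offenses: list[str]) -> dict:
    if not isinstance(obj, dict):
        offenses.append(f"{what} must be an object, got {type(obj).__name__}")
        return {}
    return obj


def loads_model(text: str, strict: bool = False) -> PathwayModel:
    """Parse a model-JSON document.

    In strict mode unknown record keys are errors; in lax mode (default)
    they are folded into the record's ``annotations``. All referential and
    structural offenses are collected and raised together.
    """
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelError([f"malformed JSON at line {exc.lineno}: {exc.msg}"]) from exc

    offenses: list[str] = []
    doc = _want_mapping(doc, "document", offenses)
    model = PathwayModel(model_id=str(doc.get("model_id", "model")))

    for i, rec in enumerate(doc.get("entities", []) or []):
        rec = _want_mapping(rec, f"entities[{i}]", offenses)
        if not rec:
            continue
        extra = set(rec) - _ENTITY_KEYS
        if extra and strict:
            offenses.append(f"entities[{i}]: unknown keys {sorted(extra)}")
        eid = rec.get("id")
        if not isinstance(eid, str) or not eid:
            offenses.append(f"entities[{i}]: missing id")
            continue
        try:
            ecls = EntityClass(rec.get("class", "Entity"))
        except ValueError:
            offenses.append(f"entity {eid!r}: unknown class {rec.get('class')!r}")
            ecls = EntityClass.ENTITY
        xrefs = []
        for x in rec.get("xrefs", []) or []:
            try:
                xrefs.append(Xref.parse(x))
            except ValueError as exc:
                offenses.append(f"entity {eid!r}: {exc}")
        ann = dict(rec.get("annotations") or {})
        ann.update({k: rec[k] for k in extra} if not strict else {})
        ent = Entity(
            id=eid,
            entity_class=ecls,
            display_name=str(rec.get("name", "")),
            cell_component=rec.get("cellComponent"),
            feature_types=frozenset(rec.get("featureTypes", []) or []),
            unification_xrefs=frozenset(xrefs),
            component_ids=tuple(rec.get("components", []) or []),
            annotations=ann,
        )
        if ent.id in model.entities:
            offenses.append(f"duplicate entity id {ent.id!r}")
        else:
            model.entities[ent.id] = ent

    for i, rec in enumerate(doc.get("processes", []) or []):
        rec = _want_mapping(rec, f"processes[{i}]", offenses)
        if not rec:
            continue
        extra = set(rec) - _PROCESS_KEYS
        if extra and strict:
            offenses.append(f"processes[{i}]: unknown keys {sorted(extra)}")
        pid = rec.get("id")
        if not isinstance(pid, str) or not pid:
            offenses.append(f"processes[{i}]: missing id")
            continue
        event = rec.get("event")
        if not isinstance(event, str):
            event = ""  # model.check() reports the missing annotation
        ann = dict(rec.get("annotations") or {})
        ann.update({k: rec[k] for k in extra} if not strict else {})
        proc = Process(
            id=pid, biological_event=event,
            display_name=str(rec.get("name", "")), annotations=ann,
        )
        if proc.id in model.processes:
            offenses.append(f"duplicate process id {proc.id!r}")
        else:
            model.processes[proc.id] = proc

    for i, rec in enumerate(doc.get("connectors", []) or []):
        rec = _want_mapping(rec, f"connectors[{i}]", offenses)
        if not rec:
            continue
        extra = set(rec) - _CONNECTOR_KEYS
        if extra and strict:
            offenses.append(f"connectors[{i}]: unknown keys {sorted(extra)}")
        cid = rec.get("id")
        if not isinstance(cid, str) or not cid:
            offenses.append(f"connectors[{i}]: missing id")
            continue
        try:
            role = ConnectorRole(rec.get("role"))
        except ValueError:
            offenses.append(f"connector {cid!r}: unknown role {rec.get('role')!r}")
            role = ConnectorRole.SUBSTRATE
        stoich = rec.get("stoichiometry", 1)
        if not isinstance(stoich, int) or isinstance(stoich, bool):
            offenses.append(
                f"connector {cid!r}: stoichiometry must be an integer, got {stoich!r}"
            )
            stoich = 1
        ann = dict(rec.get("annotations") or {})
        ann.update({k: rec[k] for k in extra} if not strict else {})
        conn = Connector(
            id=cid, role=role,
            process_id=str(rec.get("process", "")),
            entity_id=str(rec.get("entity", "")),
            stoichiometry=stoich, annotations=ann,
        )
        if conn.id in model.connectors:
            offenses.append(f"duplicate connector id {conn.id!r}")
        else:
            model.connectors[conn.id] = conn

    try:
        model.check()
    except ModelError as exc:
        offenses.extend(exc.offenses)
    if offenses:
        raise ModelError(offenses)
    return model


def load_model(path_or_stream, strict: bool = False) -> PathwayModel:
    if hasattr(path_or_stream, "read"):
        return loads_model(path_or_stream.read(), strict=strict)
    with open(path_or_stream, encoding="utf-8") as fh:
        return loads_model(fh.read(), strict=strict)


# ---------------------------------------------------------------------------
# GraphML export (visual inspection; networkx handles the format)


def to_graphml(model: PathwayModel) -> str:
    import networkx as nx

    g = nx.DiGraph()
    for e in model.entities.values():
        g.add_node(
            e.id, kind="entity", entity_class=e.entity_class.value,
            label=e.display_name or e.id,
        )
    for p in model.processes.values():
        g.add_node(
            p.id, kind="process", event=p.biological_event,
            label=p.display_name or p.id,
        )
    for c in sorted(model.connectors.values(), key=lambda c: c.id):
        if c.role is ConnectorRole.PRODUCT:
            u, v = c.process_id, c.entity_id
        else:
            u, v = c.entity_id, c.process_id
        g.add_edge(u, v, role=c.role.value, connector=c.id,
                   stoichiometry=c.stoichiometry)
    return "\n".join(nx.generate_graphml(g)) + "\n"
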