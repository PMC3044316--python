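"""Event-specific validation: declarative constraints per biological event.

Each rule-covered biological event carries an :class:`EventConstraint`
combining four kinds of clause, evaluated in fixed order:

1. **cardinality** — how many entities participate in each role;
2. **type** — required molecule classes (all of a role, or at least one);
3. **property** — required values of feature type, cellular location,
   stoichiometric coefficient, or presence of a unification xref;
4. **property relationship** — values of one property compared across two
   roles (same external reference for modified forms of one molecule,
   different cellular locations for transport).

The 36 shipped constraints fall into five groups sharing a template:

* group 1 (11 events) — cardinality + type (binding, dissociation,
  degradation, cleavage, metabolic reaction, ...);
* group 2 (15 events) — cardinality + sequence-feature property: each
  post-translational modification maps one-to-one onto the feature type its
  product must carry, and the product must share the substrate's external
  reference (it is a modified form of the same molecule);
* group 3 (3 events) — cardinality + stoichiometry: the chemical union of
  identical molecules, with the substrate coefficient 2 for dimerization,
  3–20 for oligomerization, and above 20 for polymerization;
* group 4 (3 events) — cardinality + cellular location (internalization,
  nuclear export, translocation);
* group 5 (4 events) — cardinality + type + cellular location
  (transcription, translation, gene expression, ion transport).

A missing participant suppresses the dependent property/relationship
clauses on that role: if the entity is not there, its properties cannot be
judged, and reporting them as well would double-count one curation mistake.

Constraints are data, not code: the shipped table
(``pathwayqc/data/constraints.json``) can be replaced or overridden, and
every record carries a provenance tag (``paper``-printed rules versus
``synthesized`` defaults reconstructed from the group templates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

from .model import PathwayModel, Connector, Entity, xrefs_share
from .report import Warning, WarningCategory
from .vocab import EntityClass, is_a

__all__ = [
    "CardinalitySpec",
    "TypeSpec",
    "PropertySpec",
    "RelationshipSpec",
    "EventConstraint",
    "ConstraintConfigError",
    "load_constraint_table",
    "default_constraint_table",
    "check_event_process",
    "check_group2",
    "check_internalization",
    "check_stoichiometry_event",
]

ROLES = ("input", "inputprocess", "output")

#: expected number of constraints per group in the shipped table
GROUP_SIZES = {1: 11, 2: 15, 3: 3, 4: 3, 5: 4}


class ConstraintConfigError(ValueError):
    """Malformed or incomplete constraint table."""


@dataclass(frozen=True)
class CardinalitySpec:
    """Participant count bounds on one role; ``max=None`` means unbounded."""

    role: str
    min: int = 0
    max: int | None = None

    def admits(self, n: int) -> bool:
        return n >= self.min and (self.max is None or n <= self.max)


@dataclass(frozen=True)
class TypeSpec:
    role: str
    required_class: EntityClass
    quantifier: str = "all"  # "all" | "at-least-one"


@dataclass(frozen=True)
class PropertySpec:
    """Required value of one property on one role's entities.

    ``property`` ∈ {feature_type, cell_component, stoichiometry,
    unification_xref}; ``requirement`` ∈ {equals-term, in-term-set,
    equals-integer, in-integer-range, must-be-present}. ``value`` holds the
    payload (a term, a term list, an integer, or a [lo, hi] pair with hi
    null for unbounded).
    """

    role: str
    property: str
    requirement: str
    value: object = None

    def admits_coefficient(self, n: int) -> bool:
        if self.requirement == "equals-integer":
            return n == self.value
        lo, hi = self.value  # type: ignore[misc]
        return n >= lo and (hi is None or n <= hi)


@dataclass(frozen=True)
class RelationshipSpec:
    """One property compared across two roles: values must be same/different."""

    role_a: str
    role_b: str
    property: str
    relation: str  # "same" | "different"


@dataclass(frozen=True)
class EventConstraint:
    event: str
    group: int
    cardinalities: tuple[CardinalitySpec, ...] = ()
    types: tuple[TypeSpec, ...] = ()
    properties: tuple[PropertySpec, ...] = ()
    relationships: tuple[RelationshipSpec, ...] = ()
    provenance: str = "synthesized"  # "paper" | "synthesized" | "user"
    self_event: bool = False

    @property
    def rule_id(self) -> str:
        return f"c2-g{self.group}-{self.event}"

    def feature_term(self) -> str | None:
        for p in self.properties:
            if p.property == "feature_type" and p.requirement == "equals-term":
                return str(p.value)
        return None

    def to_json(self) -> dict:
        return {
            "event": self.event,
            "group": self.group,
            "provenance": self.provenance,
            "self_event": self.self_event,
            "cardinalities": [
                {"role": c.role, "min": c.min, "max": c.max}
                for c in self.cardinalities
            ],
            "types": [
                {"role": t.role, "class": t.required_class.value,
                 "quantifier": t.quantifier}
                for t in self.types
            ],
            "properties": [
                {"role": p.role, "property": p.property,
                 "requirement": p.requirement, "value": p.value}
                for p in self.properties
            ],
            "relationships": [
                {"role_a": r.role_a, "role_b": r.role_b,
                 "property": r.property, "relation": r.relation}
                for r in self.relationships
            ],
        }


# ---------------------------------------------------------------------------
# Constraint table loading


def _parse_constraint(rec: dict, where: str) -> EventConstraint:
    def fail(msg: str):
        raise ConstraintConfigError(f"{where}: {msg}")

    event = rec.get("event")
    if not event:
        fail("missing event")
    group = rec.get("group")
    if group not in (1, 2, 3, 4, 5):
        fail(f"unknown group {group!r}")
    cards = []
    for c in rec.get("cardinalities", []):
        if c.get("role") not in ROLES:
            fail(f"unknown role {c.get('role')!r}")
        mn = int(c.get("min", 0))
        mx = c.get("max")
        mx = None if mx is None else int(mx)
        if mx is not None and mn > mx:
            fail(f"cardinality min {mn} > max {mx}")
        cards.append(CardinalitySpec(c["role"], mn, mx))
    types = []
    for t in rec.get("types", []):
        if t.get("role") not in ROLES:
            fail(f"unknown role {t.get('role')!r}")
        try:
            cls = EntityClass(t["class"])
        except (KeyError, ValueError):
            fail(f"unknown class {t.get('class')!r}")
        q = t.get("quantifier", "all")
        if q not in ("all", "at-least-one"):
            fail(f"unknown quantifier {q!r}")
        types.append(TypeSpec(t["role"], cls, q))
    props = []
    for p in rec.get("properties", []):
        if p.get("role") not in ROLES:
            fail(f"unknown role {p.get('role')!r}")
        prop, req = p.get("property"), p.get("requirement")
        if prop not in ("feature_type", "cell_component", "stoichiometry",
                        "unification_xref"):
            fail(f"unknown property {prop!r}")
        if req not in ("equals-term", "in-term-set", "equals-integer",
                       "in-integer-range", "must-be-present"):
            fail(f"unknown requirement {req!r}")
        value = p.get("value")
        if req == "equals-integer" and not isinstance(value, int):
            fail("equals-integer needs an integer value")
        if req == "in-integer-range":
            if (not isinstance(value, (list, tuple)) or len(value) != 2):
                fail("in-integer-range needs [lo, hi]")
            value = (int(value[0]), None if value[1] is None else int(value[1]))
        if req == "in-term-set":
            value = tuple(value or ())
        props.append(PropertySpec(p["role"], prop, req, value))
    rels = []
    for r in rec.get("relationships", []):
        for key in ("role_a", "role_b"):
            if r.get(key) not in ROLES:
                fail(f"unknown role {r.get(key)!r}")
        if r.get("property") not in ("cell_component", "unification_xref"):
            fail(f"unknown relationship property {r.get('property')!r}")
        if r.get("relation") not in ("same", "different"):
            fail(f"unknown relation {r.get('relation')!r}")
        rels.append(RelationshipSpec(r["role_a"], r["role_b"],
                                     r["property"], r["relation"]))
    return EventConstraint(
        event=event,
        group=group,
        cardinalities=tuple(cards),
        types=tuple(types),
        properties=tuple(props),
        relationships=tuple(rels),
        provenance=rec.get("provenance", "user"),
        self_event=bool(rec.get("self_event", False)),
    )


def load_constraint_table(
    source, strict: bool = True
) -> tuple[dict[str, EventConstraint], dict[str, str]]:
    """Load an event-constraint table plus the event→feature-type map.

    *source* is a JSON text/stream/path. In strict mode the table must hold
    exactly the 36-event roster with group sizes (11, 15, 3, 3, 4) and a
    feature map total on group 2. Returns ``(constraints_by_event,
    feature_map)``.
    """
    if hasattr(source, "read"):
        text = source.read()
    elif isinstance(source, str) and source.lstrip().startswith("{"):
        text = source
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConstraintConfigError(f"malformed JSON: {exc}") from exc

    constraints: dict[str, EventConstraint] = {}
    for i, rec in enumerate(doc.get("constraints", [])):
        con = _parse_constraint(rec, f"constraints[{i}]")
        if con.event in constraints:
            raise ConstraintConfigError(
                f"constraints[{i}]: duplicate event {con.event}"
            )
        constraints[con.event] = con

    feature_map = dict(doc.get("feature_map", {}))

    if strict:
        sizes: dict[int, int] = {}
        for con in constraints.values():
            sizes[con.group] = sizes.get(con.group, 0) + 1
        if len(constraints) != sum(GROUP_SIZES.values()):
            raise ConstraintConfigError(
                f"expected {sum(GROUP_SIZES.values())} constraints, "
                f"got {len(constraints)}"
            )
        if sizes != GROUP_SIZES:
            raise ConstraintConfigError(
                f"group sizes {sizes} != expected {GROUP_SIZES}"
            )
        for con in constraints.values():
            if con.group == 2 and con.event not in feature_map:
                raise ConstraintConfigError(
                    f"group-2 event {con.event} missing from feature_map"
                )
    return constraints, feature_map


def default_constraint_table() -> tuple[dict[str, EventConstraint], dict[str, str]]:
    """The shipped constraint table (``pathwayqc/data/constraints.json``)."""
    ref = resources.files("pathwayqc").joinpath("data/constraints.json")
    return load_constraint_table(ref.read_text(encoding="utf-8"), strict=True)


# ---------------------------------------------------------------------------
# Clause evaluation

_CARDINALITY_CATEGORY = {
    "input": WarningCategory.WRONG_CARDINALITY_INPUT,
    "inputprocess": WarningCategory.WRONG_CARDINALITY_INPUTPROCESS,
    "output": WarningCategory.WRONG_CARDINALITY_OUTPUT,
}
_MISSING_CATEGORY = {
    "inputprocess": WarningCategory.MISSING_INPUTPROCESS,
    "output": WarningCategory.MISSING_OUTPUT,
}


def _role_participants(
    model: PathwayModel, process_id: str
) -> dict[str, list[tuple[Entity, Connector]]]:
    return {
        "input": model.has_input(process_id),
        "inputprocess": model.has_inputprocess(process_id),
        "output": model.has_output(process_id),
    }


def check_event_process(
    model: PathwayModel, process_id: str, constraint: EventConstraint
) -> list[Warning]:
    """Evaluate one event constraint against one process.

    Clauses run in fixed order (cardinality, type, property, relationship);
    each violated clause yields one warning per offending category, with
    all offending entities of the clause listed together. Roles emptied in
    violation of a lower cardinality bound are marked missing and their
    dependent clauses are suppressed.
    """
    process = model.processes.get(process_id)
    if process is None:
        raise KeyError(f"unknown process id {process_id!r}")
    if process.biological_event != constraint.event:
        raise ValueError(
            f"process {process_id!r} carries {process.biological_event!r}, "
            f"constraint is for {constraint.event!r}"
        )

    parts = _role_participants(model, process_id)
    rule_id = constraint.rule_id
    event = constraint.event
    warnings: list[Warning] = []
    missing_roles: set[str] = set()

    def warn(category: WarningCategory, message: str,
             entity_ids: Iterable[str] = ()) -> None:
        warnings.append(Warning(
            category=category, rule_id=rule_id, message=message,
            process_id=process_id,
            entity_ids=tuple(sorted(set(entity_ids))), event_term=event,
        ))

    # 1. cardinality
    for spec in constraint.cardinalities:
        n = len(parts[spec.role])
        if spec.admits(n):
            continue
        if n == 0 and spec.min >= 1:
            missing_roles.add(spec.role)
            if spec.role in _MISSING_CATEGORY:
                warn(_MISSING_CATEGORY[spec.role],
                     f"{event} requires {spec.role} entities but none are defined")
                continue
        bound = (f"exactly {spec.min}" if spec.min == spec.max
                 else f"between {spec.min} and {spec.max}" if spec.max is not None
                 else f"at least {spec.min}")
        warn(_CARDINALITY_CATEGORY[spec.role],
             f"{event} requires {bound} {spec.role} entities, found {n}",
             (e.id for e, _ in parts[spec.role]))

    def role_ok(role: str) -> bool:
        # the "input" family subsumes inputprocess: a missing inputprocess
        # role leaves input-role clauses evaluable only on what is present
        return role not in missing_roles and bool(parts[role])

    # 2. type
    for spec in constraint.types:
        if spec.role in missing_roles or not parts[spec.role]:
            continue
        entities = [e for e, _ in parts[spec.role]]
        if spec.quantifier == "all":
            offenders = [e for e in entities
                         if not is_a(e.entity_class, spec.required_class)]
            if not offenders:
                continue
            undeclared = all(o.entity_class is EntityClass.ENTITY for o in offenders)
            warn(
                WarningCategory.MISSING_TYPE if undeclared
                else WarningCategory.WRONG_TYPE,
                f"{event}: every {spec.role} entity must be "
                f"{spec.required_class.value}",
                (o.id for o in offenders),
            )
        else:  # at-least-one
            if any(is_a(e.entity_class, spec.required_class) for e in entities):
                continue
            undeclared = all(e.entity_class is EntityClass.ENTITY for e in entities)
            warn(
                WarningCategory.MISSING_TYPE if undeclared
                else WarningCategory.WRONG_TYPE,
                f"{event}: at least one {spec.role} entity must be "
                f"{spec.required_class.value}",
                (e.id for e in entities),
            )

    # 3. property
    for spec in constraint.properties:
        if spec.role in missing_roles or not parts[spec.role]:
            continue
        pairs = parts[spec.role]
        if spec.property == "feature_type":
            # satisfied if any entity of the role carries the term
            term = str(spec.value)
            if not any(term in e.feature_types for e, _ in pairs):
                warn(WarningCategory.MISSING_FEATURETYPE,
                     f"{event}: {spec.role} entity must carry feature {term}",
                     (e.id for e, _ in pairs))
        elif spec.property == "cell_component":
            absent = [e for e, _ in pairs if e.cell_component is None]
            if absent:
                warn(WarningCategory.MISSING_CELLCOMPONENT,
                     f"{event}: {spec.role} entity has no cellular location",
                     (e.id for e in absent))
            if spec.requirement == "must-be-present":
                continue
            allowed = ((str(spec.value),) if spec.requirement == "equals-term"
                       else tuple(spec.value))
            wrong = [e for e, _ in pairs
                     if e.cell_component is not None
                     and e.cell_component not in allowed]
            if wrong:
                warn(WarningCategory.WRONG_CELLCOMPONENT,
                     f"{event}: {spec.role} entity must be located in "
                     f"{' or '.join(allowed)}",
                     (e.id for e in wrong))
        elif spec.property == "stoichiometry":
            bad = [(e, c) for e, c in pairs
                   if not spec.admits_coefficient(c.stoichiometry)]
            if bad:
                warn(WarningCategory.WRONG_STOICHIOMETRY,
                     f"{event}: {spec.role} stoichiometric coefficient "
                     f"{', '.join(str(c.stoichiometry) for _, c in bad)} "
                     f"outside the admissible set",
                     (e.id for e, _ in bad))
        elif spec.property == "unification_xref":
            bare = [e for e, _ in pairs if not e.unification_xrefs]
            if bare:
                warn(WarningCategory.MISSING_UNIFICATIONXREF,
                     f"{event}: {spec.role} entity has no external reference",
                     (e.id for e in bare))

    # 4. property relationship
    for spec in constraint.relationships:
        if not role_ok(spec.role_a) or not role_ok(spec.role_b):
            continue
        side_a = [e for e, _ in parts[spec.role_a]]
        side_b = [e for e, _ in parts[spec.role_b]]
        if spec.property == "unification_xref":
            bare = [e for e in side_a + side_b if not e.unification_xrefs]
            if bare:
                warn(WarningCategory.MISSING_UNIFICATIONXREF,
                     f"{event}: external references needed to compare "
                     f"{spec.role_a} and {spec.role_b} entities are not defined",
                     (e.id for e in bare))
                continue  # sameAs cannot be judged
            if spec.relation == "same":
                mism = [b for b in side_b
                        if not any(xrefs_share(a.unification_xrefs,
                                               b.unification_xrefs)
                                   for a in side_a)]
                if mism:
                    warn(WarningCategory.WRONG_UNIFICATIONXREF,
                         f"{event}: {spec.role_b} entity does not share an "
                         f"external reference with any {spec.role_a} entity",
                         (e.id for e in mism))
        elif spec.property == "cell_component":
            placed_a = [e for e in side_a if e.cell_component is not None]
            placed_b = [e for e in side_b if e.cell_component is not None]
            if not placed_a or not placed_b:
                continue  # absence is the property clauses' business
            if spec.relation == "different":
                clashes = [(a, b) for a in placed_a for b in placed_b
                           if a.cell_component == b.cell_component]
                if clashes:
                    ids = {e.id for pair in clashes for e in pair}
                    warn(WarningCategory.SAME_CELLCOMPONENT_SHOULD_DIFFER,
                         f"{event}: {spec.role_a} and {spec.role_b} entities "
                         f"must have different cellular locations",
                         ids)
            else:  # same
                mism = [(a, b) for a in placed_a for b in placed_b
                        if a.cell_component != b.cell_component]
                if mism:
                    ids = {e.id for pair in mism for e in pair}
                    warn(WarningCategory.WRONG_CELLCOMPONENT,
                         f"{event}: {spec.role_a} and {spec.role_b} entities "
                         f"must share a cellular location",
                         ids)
    return warnings


# -- named specializations ---------------------------------------------------
# The three entry points below are the group-specific faces of the generic
# clause evaluator; they validate their precondition and delegate.


def check_group2(
    model: PathwayModel,
    process_id: str,
    constraint: EventConstraint,
    feature_map: dict[str, str] | None = None,
) -> list[Warning]:
    """Post-translational modification check (group 2).

    The product must carry the feature type mapped from the event and share
    the substrate's external reference; self-events (autophosphorylation)
    additionally admit no enzyme, i.e. exactly one input entity in total.
    """
    if constraint.group != 2:
        raise ValueError(f"{constraint.event} is not a group-2 event")
    if feature_map is not None:
        if constraint.event not in feature_map:
            raise ConstraintConfigError(
                f"event {constraint.event} has no feature-type mapping"
            )
        term = feature_map[constraint.event]
        props = tuple(
            PropertySpec(p.role, p.property, p.requirement, term)
            if p.property == "feature_type" else p
            for p in constraint.properties
        )
        constraint = EventConstraint(
            event=constraint.event, group=constraint.group,
            cardinalities=constraint.cardinalities, types=constraint.types,
            properties=props, relationships=constraint.relationships,
            provenance=constraint.provenance, self_event=constraint.self_event,
        )
    return check_event_process(model, process_id, constraint)


def check_internalization(model: PathwayModel, process_id: str,
                          constraint: EventConstraint) -> list[Warning]:
    """Movement from the cell surface into the cytosol (group 4): substrate
    located extracellularly or at the plasma membrane, product in the
    cytosol, both forms of one molecule (shared external reference)."""
    if constraint.event != "ME_Internalization":
        raise ValueError("constraint is not the internalization rule")
    return check_event_process(model, process_id, constraint)


def check_stoichiometry_event(model: PathwayModel, process_id: str,
                              constraint: EventConstraint) -> list[Warning]:
    """Dimerization/oligomerization/polymerization (group 3): one substrate
    whose coefficient lies in {2}, {3..20} or {21..}, one Complex product."""
    if constraint.group != 3:
        raise ValueError(f"{constraint.event} is not a group-3 event")
    return check_event_process(model, process_id, constraint)
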