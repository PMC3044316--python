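"""Synthetic pathway-model generator.

Builds models for testing and demonstration, in four flavours:

* clean models — every process constructed to satisfy its event's shipped
  constraint (constructive soundness: validation reports zero warnings);
* targeted single-violation models — a clean model with an exact, post-hoc
  verified number of defects per warning category injected;
* the two worked correction cases (a misassigned connector role on an
  activation, and a binding mislabeled as dimerization);
* randomized stress fixtures with event frequencies skewed the way real
  curation load is (binding and activation events dominate).

Generation is a pure function of the spec: one integer seed drives an
integer-only RNG, so the same spec yields byte-identical models on any
platform.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from . import events as _events
from .events import EventConstraint, PropertySpec
from .model import (
    Connector,
    ConnectorRole,
    Entity,
    PathwayModel,
    Process,
    Xref,
)
from .report import Warning, WarningCategory
from .structural import check_valid_connections
from .vocab import CC_TERMS, EntityClass

__all__ = [
    "FixtureSpec",
    "GenerationError",
    "make_clean_model",
    "inject_violations",
    "generate",
    "make_case_models",
    "DEFAULT_EVENT_WEIGHTS",
]


class GenerationError(ValueError):
    """The requested fixture cannot be built."""


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    n_processes: int = 10
    event_palette: tuple[str, ...] = ()
    violation_plan: tuple[tuple[str, int], ...] = ()
    model_id: str = "fixture"


#: sampling weights loosely shaped like real curation load, where binding
#: and unknown-activation events dominate
DEFAULT_EVENT_WEIGHTS: dict[str, int] = {
    "ME_Binding": 19,
    "ME_UnknownActivation": 8,
    "ME_GeneExpression": 7,
    "ME_Phosphorylation": 5,
    "ME_Translation": 4,
    "ME_Translocation": 2,
    "ME_Ubiquitination": 1,
    "ME_Dimerization": 1,
}


def _weighted_choice(rng: random.Random, items: Sequence[str],
                     weights: dict[str, int]) -> str:
    tot = sum(weights.get(i, 1) for i in items)
    r = rng.randrange(tot)
    for i in items:
        r -= weights.get(i, 1)
        if r < 0:
            return i
    return items[-1]


# ---------------------------------------------------------------------------
# Clean construction


def _default_cc(spec: PropertySpec) -> str:
    if spec.requirement == "equals-term":
        return str(spec.value)
    if spec.requirement == "in-term-set":
        return spec.value[0]
    return "CC_Cytosol"  # must-be-present


def _build_compliant_process(
    model: PathwayModel,
    pid: str,
    constraint: EventConstraint,
    serial: int,
) -> None:
    """Add one process plus fresh participant entities satisfying every
    clause of *constraint*."""
    model.add_process(Process(id=pid, biological_event=constraint.event,
                              display_name=constraint.event.removeprefix("ME_")))

    def bound(role: str) -> int:
        return max((c.min for c in constraint.cardinalities if c.role == role),
                   default=0)

    n_ip = bound("inputprocess")
    n_out = bound("output")
    n_extra_in = max(0, bound("input") - n_ip)

    roles_entities: dict[str, list[Entity]] = {"inputprocess": [], "output": []}
    connectors: dict[str, list[Connector]] = {"inputprocess": [], "output": []}
    extra_inputs: list[Entity] = []

    def add(role: ConnectorRole, key: str | None, tag: str, i: int) -> Entity:
        ent = model.add_entity(Entity(
            id=f"{pid}_{tag}{i}", entity_class=EntityClass.PROTEIN,
            display_name=f"{tag}{i}",
        ))
        conn = model.add_connector(Connector(
            id=f"{pid}_c_{tag}{i}", role=role,
            process_id=pid, entity_id=ent.id,
        ))
        if key is not None:
            roles_entities[key].append(ent)
            connectors[key].append(conn)
        return ent

    for i in range(n_ip):
        add(ConnectorRole.SUBSTRATE, "inputprocess", "sub", i)
    for i in range(n_extra_in):
        extra_inputs.append(add(ConnectorRole.ACTIVATOR, None, "act", i))
    for i in range(n_out):
        add(ConnectorRole.PRODUCT, "output", "out", i)

    def family(role: str) -> list[Entity]:
        if role == "input":
            return roles_entities["inputprocess"] + extra_inputs
        return roles_entities[role]

    for tspec in constraint.types:
        targets = family(tspec.role)
        if not targets:
            continue
        if tspec.quantifier == "all":
            for e in targets:
                e.entity_class = tspec.required_class
        else:
            targets[0].entity_class = tspec.required_class

    for pspec in constraint.properties:
        targets = family(pspec.role)
        if pspec.property == "cell_component":
            for e in targets:
                e.cell_component = _default_cc(pspec)
        elif pspec.property == "feature_type":
            for e in targets:
                e.feature_types = e.feature_types | {str(pspec.value)}
        elif pspec.property == "stoichiometry":
            coeff = (pspec.value if pspec.requirement == "equals-integer"
                     else pspec.value[0])
            for c in connectors.get(pspec.role, []):
                c.stoichiometry = int(coeff)
        elif pspec.property == "unification_xref":
            for e in targets:
                if not e.unification_xrefs:
                    e.unification_xrefs = frozenset(
                        {Xref("TRANSPATH", f"T{serial}_{e.id}")}
                    )

    for rspec in constraint.relationships:
        side_a, side_b = family(rspec.role_a), family(rspec.role_b)
        if rspec.property == "unification_xref":
            shared = frozenset({Xref("TRANSPATH", f"T{serial}")})
            for e in side_a + side_b:
                e.unification_xrefs = e.unification_xrefs | shared
        elif rspec.property == "cell_component" and rspec.relation == "different":
            for e in side_b:
                if any(a.cell_component == e.cell_component for a in side_a):
                    taken = {a.cell_component for a in side_a}
                    e.cell_component = next(
                        t for t in CC_TERMS if t not in taken
                    )
        elif rspec.property == "cell_component" and rspec.relation == "same":
            if side_a and side_a[0].cell_component is not None:
                for e in side_b:
                    e.cell_component = side_a[0].cell_component


def make_clean_model(
    spec: FixtureSpec,
    constraints: dict[str, EventConstraint] | None = None,
) -> PathwayModel:
    """Build a model in which every process satisfies its event constraint.

    Events are drawn from ``spec.event_palette`` (default: all 36 covered
    events) with curation-load-like weights. Events in the palette without
    a constraint are a generation error — clean construction needs a
    template to satisfy.
    """
    if spec.violation_plan:
        raise GenerationError("clean model requested with a violation plan")
    if constraints is None:
        constraints, _ = _events.default_constraint_table()
    palette = tuple(spec.event_palette) or tuple(sorted(constraints))
    missing = [e for e in palette if e not in constraints]
    if missing:
        raise GenerationError(f"no constraint for palette events {missing}")

    rng = random.Random(spec.seed)
    model = PathwayModel(model_id=spec.model_id)
    for k in range(spec.n_processes):
        event = _weighted_choice(rng, palette, DEFAULT_EVENT_WEIGHTS)
        _build_compliant_process(model, f"p{k:04d}", constraints[event], k)
    model.check()
    return model


# ---------------------------------------------------------------------------
# Violation injection

_Mutation = Callable[[PathwayModel], None]


def _process_warnings(model: PathwayModel, pid: str,
                      constraints: dict[str, EventConstraint]) -> list[Warning]:
    event = model.processes[pid].biological_event
    out: list[Warning] = []
    con = constraints.get(event)
    if con is not None:
        out.extend(_events.check_event_process(model, pid, con))
    out.extend(w for w in check_valid_connections(model) if w.process_id == pid)
    return out


def _wrong_class(required: EntityClass) -> EntityClass:
    for cls in (EntityClass.PROTEIN, EntityClass.SMALL_MOLECULE, EntityClass.DNA):
        if cls is not required:
            return cls
    raise AssertionError


def _candidate_mutations(
    model: PathwayModel, pid: str, category: WarningCategory,
    constraints: dict[str, EventConstraint], serial: int,
) -> Iterable[_Mutation]:
    """Yield mutations of process *pid* expected to raise *category* once."""
    con = constraints.get(model.processes[pid].biological_event)
    if con is None:
        return
    cards = {c.role: c for c in con.cardinalities}
    subs = [c for c in model.connectors_of(pid)
            if c.role is ConnectorRole.SUBSTRATE]
    outs = [c for c in model.connectors_of(pid)
            if c.role is ConnectorRole.PRODUCT]

    def copy_xrefs(conns):
        for c in conns:
            x = model.entities[c.entity_id].unification_xrefs
            if x:
                return x
        return frozenset({Xref("TRANSPATH", f"X{serial}")})

    def add_participant(role: ConnectorRole, role_key: str):
        def mut(m: PathwayModel) -> None:
            ent = m.add_entity(Entity(
                id=f"{pid}_inj{serial}", entity_class=EntityClass.PROTEIN,
                display_name=f"injected {serial}",
            ))
            conn = m.add_connector(Connector(
                id=f"{pid}_injc{serial}", role=role,
                process_id=pid, entity_id=ent.id,
            ))
            for tspec in con.types:
                if tspec.role == role_key and tspec.quantifier == "all":
                    ent.entity_class = tspec.required_class
            for pspec in con.properties:
                if pspec.role != role_key:
                    continue
                if pspec.property == "cell_component":
                    ent.cell_component = _default_cc(pspec)
                elif pspec.property == "feature_type":
                    ent.feature_types = ent.feature_types | {str(pspec.value)}
                elif pspec.property == "stoichiometry":
                    conn.stoichiometry = int(
                        pspec.value if pspec.requirement == "equals-integer"
                        else pspec.value[0]
                    )
            ent.unification_xrefs = copy_xrefs(
                subs if role is ConnectorRole.SUBSTRATE else outs
            )
            for rspec in con.relationships:
                if (rspec.property == "cell_component"
                        and rspec.relation == "different"
                        and role_key in (rspec.role_a, rspec.role_b)):
                    other = (rspec.role_a if role_key == rspec.role_b
                             else rspec.role_b)
                    other_conns = subs if other == "inputprocess" else outs
                    taken = {m.entities[c.entity_id].cell_component
                             for c in other_conns}
                    if ent.cell_component in taken:
                        ent.cell_component = next(
                            t for t in CC_TERMS if t not in taken)
        return mut

    def at_max(role: str, n_present: int) -> bool:
        # adding one participant must push the count past the upper bound
        return (role in cards and cards[role].max is not None
                and n_present == cards[role].max)

    n_inputs = len(model.has_input(pid))

    if category is WarningCategory.WRONG_CARDINALITY_INPUT:
        if at_max("input", n_inputs):
            yield add_participant(ConnectorRole.ACTIVATOR, "input")

    elif category is WarningCategory.WRONG_CARDINALITY_INPUTPROCESS:
        if at_max("inputprocess", len(subs)) and "input" not in cards:
            yield add_participant(ConnectorRole.SUBSTRATE, "inputprocess")

    elif category is WarningCategory.WRONG_CARDINALITY_OUTPUT:
        if at_max("output", len(outs)):
            yield add_participant(ConnectorRole.PRODUCT, "output")

    elif category is WarningCategory.MISSING_INPUTPROCESS:
        if ("inputprocess" in cards and cards["inputprocess"].min >= 1
                and "input" not in cards and subs):
            def drop_subs(m: PathwayModel) -> None:
                for c in subs:
                    del m.connectors[c.id]
            yield drop_subs

    elif category is WarningCategory.MISSING_OUTPUT:
        if "output" in cards and cards["output"].min >= 1 and outs:
            def drop_outs(m: PathwayModel) -> None:
                for c in outs:
                    del m.connectors[c.id]
            yield drop_outs

    elif category in (WarningCategory.WRONG_TYPE, WarningCategory.MISSING_TYPE):
        for tspec in con.types:
            if tspec.quantifier != "all":
                continue
            conns = subs if tspec.role == "inputprocess" else (
                outs if tspec.role == "output" else [])
            for c in conns:
                eid = c.entity_id
                newcls = (_wrong_class(tspec.required_class)
                          if category is WarningCategory.WRONG_TYPE
                          else EntityClass.ENTITY)

                def retype(m: PathwayModel, eid=eid, newcls=newcls) -> None:
                    m.entities[eid].entity_class = newcls
                    m.entities[eid].component_ids = ()
                yield retype

    elif category is WarningCategory.WRONG_CELLCOMPONENT:
        for pspec in con.properties:
            if pspec.property != "cell_component" or \
                    pspec.requirement == "must-be-present":
                continue
            allowed = ((str(pspec.value),) if pspec.requirement == "equals-term"
                       else tuple(pspec.value))
            off_term = next(t for t in CC_TERMS if t not in allowed)
            conns = subs if pspec.role == "inputprocess" else outs
            for c in conns:
                def relocate(m: PathwayModel, eid=c.entity_id,
                             term=off_term) -> None:
                    m.entities[eid].cell_component = term
                yield relocate

    elif category is WarningCategory.MISSING_CELLCOMPONENT:
        for pspec in con.properties:
            if pspec.property != "cell_component":
                continue
            conns = subs if pspec.role == "inputprocess" else outs
            for c in conns:
                def unplace(m: PathwayModel, eid=c.entity_id) -> None:
                    m.entities[eid].cell_component = None
                yield unplace

    elif category is WarningCategory.MISSING_FEATURETYPE:
        term = con.feature_term()
        if term:
            for c in outs:
                def defeature(m: PathwayModel, eid=c.entity_id,
                              term=term) -> None:
                    e = m.entities[eid]
                    e.feature_types = e.feature_types - {term}
                yield defeature

    elif category is WarningCategory.WRONG_STOICHIOMETRY:
        for pspec in con.properties:
            if pspec.property != "stoichiometry":
                continue
            bad = (pspec.value + 1 if pspec.requirement == "equals-integer"
                   else pspec.value[0] - 1)
            for c in subs:
                def recoeff(m: PathwayModel, cid=c.id, bad=int(bad)) -> None:
                    m.connectors[cid].stoichiometry = bad
                yield recoeff

    elif category is WarningCategory.MISSING_UNIFICATIONXREF:
        if any(r.property == "unification_xref" for r in con.relationships):
            for c in subs:
                def strip_xref(m: PathwayModel, eid=c.entity_id) -> None:
                    m.entities[eid].unification_xrefs = frozenset()
                yield strip_xref

    elif category is WarningCategory.WRONG_UNIFICATIONXREF:
        if any(r.property == "unification_xref" and r.relation == "same"
               for r in con.relationships):
            for c in outs:
                def rewire_xref(m: PathwayModel, eid=c.entity_id) -> None:
                    m.entities[eid].unification_xrefs = frozenset(
                        {Xref("TRANSPATH", f"MISMATCH{serial}")}
                    )
                yield rewire_xref

    elif category is WarningCategory.SAME_CELLCOMPONENT_SHOULD_DIFFER:
        if any(r.property == "cell_component" and r.relation == "different"
               for r in con.relationships) and subs and outs:
            def collide(m: PathwayModel) -> None:
                src = m.entities[subs[0].entity_id].cell_component
                for c in outs:
                    m.entities[c.entity_id].cell_component = src
            yield collide

    elif category is WarningCategory.INVALID_CONNECTION:
        if "input" not in cards and subs:
            def duplicate(m: PathwayModel) -> None:
                ref = subs[0]
                m.add_connector(Connector(
                    id=f"{pid}_dupc{serial}", role=ConnectorRole.INHIBITOR,
                    process_id=pid, entity_id=ref.entity_id,
                ))
            yield duplicate


def inject_violations(
    model: PathwayModel,
    plan: dict[WarningCategory | str, int] | Iterable[tuple[str, int]],
    seed: int = 0,
    constraints: dict[str, EventConstraint] | None = None,
) -> PathwayModel:
    """Return a copy of *model* with exactly the planned violations.

    Each injection touches a distinct process and is verified in isolation
    (the process must have been clean for the category and must afterwards
    yield the category exactly once, with no collateral warnings); the
    whole plan is re-verified on the final model. An unachievable plan is a
    :class:`GenerationError`.
    """
    if constraints is None:
        constraints, _ = _events.default_constraint_table()
    plan_items: list[tuple[WarningCategory, int]] = []
    items = plan.items() if isinstance(plan, dict) else plan
    for cat, n in items:
        plan_items.append((WarningCategory(cat), int(n)))

    rng = random.Random(seed)
    work = model.copy()
    used: set[str] = set()
    serial = 0

    for category, count in plan_items:
        for _ in range(count):
            pids = [p for p in sorted(work.processes) if p not in used]
            rng.shuffle(pids)
            injected = False
            for pid in pids:
                if _process_warnings(work, pid, constraints):
                    continue  # not clean for this process: skip
                for mutation in _candidate_mutations(
                        work, pid, category, constraints, serial):
                    trial = work.copy()
                    mutation(trial)
                    trial.check()
                    got = _process_warnings(trial, pid, constraints)
                    if [w.category for w in got] == [category]:
                        work = trial
                        used.add(pid)
                        serial += 1
                        injected = True
                        break
                if injected:
                    break
            if not injected:
                raise GenerationError(
                    f"cannot inject {category.value} into model "
                    f"{model.model_id!r}: no applicable clean process"
                )

    # whole-plan post-hoc check
    all_warnings: list[Warning] = list(check_valid_connections(work))
    for pid in sorted(work.processes):
        event = work.processes[pid].biological_event
        if event in constraints:
            all_warnings.extend(
                _events.check_event_process(work, pid, constraints[event])
            )
    want_counts: dict[WarningCategory, int] = {}
    for cat, n in plan_items:
        want_counts[cat] = want_counts.get(cat, 0) + n
    got: dict[WarningCategory, int] = {}
    for w in all_warnings:
        got[w.category] = got.get(w.category, 0) + 1
    if got != want_counts:
        raise GenerationError(
            f"injection verification failed: wanted {want_counts}, got {got}"
        )
    return work


def generate(spec: FixtureSpec,
             constraints: dict[str, EventConstraint] | None = None
             ) -> PathwayModel:
    """Clean model per *spec*, with its violation plan (if any) injected."""
    clean_spec = FixtureSpec(
        seed=spec.seed, n_processes=spec.n_processes,
        event_palette=spec.event_palette, model_id=spec.model_id,
    )
    model = make_clean_model(clean_spec, constraints)
    if spec.violation_plan:
        model = inject_violations(model, spec.violation_plan,
                                  seed=spec.seed + 1, constraints=constraints)
    return model


# ---------------------------------------------------------------------------
# Worked correction cases


def make_case_models() -> tuple[PathwayModel, PathwayModel,
                                PathwayModel, PathwayModel]:
    """The two worked curation-mistake cases plus their corrections.

    Case 1: an unknown-activation with the already-active kinase wired as a
    second substrate instead of an activator — one substrate-cardinality
    warning; fixed by changing the connector role.

    Case 2: a receptor-complex binding misannotated as dimerization (a
    dimerization unites identical molecules, so it takes exactly one
    substrate) — one substrate-cardinality warning; fixed by relabeling
    the event as binding. Non-focal clauses (xrefs, features, coefficients)
    are satisfied so the demonstrated warning is isolated.
    """
    def case1(fixed: bool) -> PathwayModel:
        m = PathwayModel(model_id="case1_fixed" if fixed else "case1")
        m.add_entity(Entity(
            id="ras_active", entity_class=EntityClass.PROTEIN,
            display_name="Ras{active}",
            feature_types=frozenset({"FT_Active"}),
            unification_xrefs=frozenset({Xref("TRANSPATH", "RAS")}),
        ))
        m.add_entity(Entity(
            id="raf1", entity_class=EntityClass.PROTEIN, display_name="Raf1",
            unification_xrefs=frozenset({Xref("TRANSPATH", "RAF1")}),
        ))
        m.add_entity(Entity(
            id="raf1_active", entity_class=EntityClass.PROTEIN,
            display_name="Raf1{active}",
            feature_types=frozenset({"FT_Active"}),
            unification_xrefs=frozenset({Xref("TRANSPATH", "RAF1")}),
        ))
        m.add_process(Process(id="act1", biological_event="ME_UnknownActivation",
                              display_name="Raf1 activation"))
        m.add_connector(Connector(
            id="c_ras", process_id="act1", entity_id="ras_active",
            role=(ConnectorRole.ACTIVATOR if fixed else ConnectorRole.SUBSTRATE),
        ))
        m.add_connector(Connector(
            id="c_raf", process_id="act1", entity_id="raf1",
            role=ConnectorRole.SUBSTRATE,
        ))
        m.add_connector(Connector(
            id="c_out", process_id="act1", entity_id="raf1_active",
            role=ConnectorRole.PRODUCT,
        ))
        m.check()
        return m

    def case2(fixed: bool) -> PathwayModel:
        m = PathwayModel(model_id="case2_fixed" if fixed else "case2")
        m.add_entity(Entity(
            id="mcsf2_r", entity_class=EntityClass.COMPLEX,
            display_name="M-CSF(2):M-CSF-1-R",
            unification_xrefs=frozenset({Xref("TRANSPATH", "MCSF-R-C1")}),
        ))
        m.add_entity(Entity(
            id="mcsf1r", entity_class=EntityClass.PROTEIN,
            display_name="M-CSF-1-R",
            unification_xrefs=frozenset({Xref("TRANSPATH", "MCSF1R")}),
        ))
        m.add_entity(Entity(
            id="mcsf2_r2", entity_class=EntityClass.COMPLEX,
            display_name="M-CSF(2):M-CSF-1-R(2)",
            unification_xrefs=frozenset({Xref("TRANSPATH", "MCSF-R-C2")}),
        ))
        m.add_process(Process(
            id="dim1",
            biological_event="ME_Binding" if fixed else "ME_Dimerization",
            display_name="receptor complex formation",
        ))
        m.add_connector(Connector(
            id="c_in1", process_id="dim1", entity_id="mcsf2_r",
            role=ConnectorRole.SUBSTRATE, stoichiometry=2,
        ))
        m.add_connector(Connector(
            id="c_in2", process_id="dim1", entity_id="mcsf1r",
            role=ConnectorRole.SUBSTRATE, stoichiometry=2,
        ))
        m.add_connector(Connector(
            id="c_out", process_id="dim1", entity_id="mcsf2_r2",
            role=ConnectorRole.PRODUCT,
        ))
        m.check()
        return m

    return case1(False), case1(True), case2(False), case2(True)
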