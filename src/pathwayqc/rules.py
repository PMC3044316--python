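"""Event-condition-action rule registry and evaluation.

The registry holds exactly 40 rules:

* 1 structural rule (criterion 1) — the valid-connection check, a pure
  condition-action rule over every (process, entity) pair;
* 36 event rules (criterion 2) — reactive rules triggered by the
  biological event annotated on a process;
* 3 complementation rules (criterion 3) — condition-action rules whose
  action *mutates* the model (adding production, binding and degradation
  processes; see :mod:`pathwayqc.complement`).

``evaluate`` is strictly report-only: criterion-1/2 actions are warnings,
and when criterion 3 is requested its conditions are evaluated but the
mutating actions are only *counted* (the report's ``complementation_needed``
side channel); run :func:`pathwayqc.complement.complement_model` to apply
them. Processes whose event has no rule are collected in the report's
``uncovered_events`` side channel — absence of a rule is not an error,
some events have no characteristics specific enough to constrain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

from . import complement as _complement
from . import events as _events
from . import structural as _structural
from .model import PathwayModel
from .report import ValidationReport, Warning

__all__ = ["Rule", "RuleRegistry", "build_registry", "default_registry",
           "evaluate", "list_rules", "uncovered_events"]


@dataclass(frozen=True)
class Rule:
    """One event-condition-action record.

    Reactive rules carry a ``trigger_event`` and fire per process bearing
    that event; pure condition-action rules (criteria 1 and 3) scan the
    whole model. ``action_kind`` is ``report`` or ``mutate``; ``condition``
    returns the warnings (report) or detected focus nodes (mutate).
    """

    rule_id: str
    criterion: int
    group: int | None = None
    trigger_event: str | None = None
    action_kind: str = "report"
    description: str = ""
    provenance: str = "paper"
    condition: Callable = field(default=lambda model: [], compare=False)

    def summary(self) -> dict:
        return {
            "rule_id": self.rule_id,
            "criterion": self.criterion,
            "group": self.group,
            "trigger_event": self.trigger_event,
            "action_kind": self.action_kind,
            "provenance": self.provenance,
            "description": self.description,
        }


@dataclass
class RuleRegistry:
    rules: list[Rule]
    constraints: dict[str, _events.EventConstraint]
    feature_map: dict[str, str]

    def __len__(self) -> int:
        return len(self.rules)

    def by_criterion(self, criterion: int) -> list[Rule]:
        return [r for r in self.rules if r.criterion == criterion]

    def event_rule(self, event_term: str) -> Rule | None:
        for r in self.rules:
            if r.criterion == 2 and r.trigger_event == event_term:
                return r
        return None


def build_registry(
    constraints: dict[str, _events.EventConstraint] | None = None,
    feature_map: dict[str, str] | None = None,
) -> RuleRegistry:
    """Assemble the 40-rule registry from a constraint table (default: the
    shipped one)."""
    if constraints is None:
        constraints, shipped_map = _events.default_constraint_table()
        feature_map = feature_map or shipped_map
    feature_map = feature_map or {}

    rules: list[Rule] = [Rule(
        rule_id=_structural.RULE_ID,
        criterion=1,
        description="each (process, entity) pair joined by at most one "
                    "connector; violations need user selection of the "
                    "correct connector",
        provenance="paper",
        condition=_structural.check_valid_connections,
    )]

    for event in sorted(constraints):
        con = constraints[event]

        def _cond(model: PathwayModel, process_id: str,
                  con: _events.EventConstraint = con) -> list[Warning]:
            return _events.check_event_process(model, process_id, con)

        rules.append(Rule(
            rule_id=con.rule_id,
            criterion=2,
            group=con.group,
            trigger_event=event,
            description=f"group-{con.group} constraints for {event}",
            provenance=con.provenance,
            condition=_cond,
        ))

    rules.append(Rule(
        rule_id="c3-starting-entity", criterion=3, action_kind="mutate",
        description="non-complex entity never produced: add an unknown "
                    "production pre-process",
        provenance="paper", condition=_complement.find_starting_entities,
    ))
    rules.append(Rule(
        rule_id="c3-starting-complex", criterion=3, action_kind="mutate",
        description="complex never produced: add a binding process over its "
                    "components",
        provenance="paper", condition=_complement.find_starting_complexes,
    ))
    rules.append(Rule(
        rule_id="c3-degrading-entity", criterion=3, action_kind="mutate",
        description="protein/complex/mRNA/small molecule without a "
                    "degradation process: add an unknown degradation",
        provenance="paper", condition=_complement.find_degrading_entities,
    ))
    return RuleRegistry(rules=rules, constraints=dict(constraints),
                        feature_map=dict(feature_map))


_DEFAULT: RuleRegistry | None = None


def default_registry() -> RuleRegistry:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = build_registry()
    return _DEFAULT


def evaluate(
    model: PathwayModel,
    registry: RuleRegistry | None = None,
    criteria: frozenset[int] | set[int] = frozenset({1, 2}),
) -> ValidationReport:
    """Run the selected criteria over *model* and return the report.

    Never mutates the model. Deterministic: warnings are sorted by
    (process, rule, category, entities).
    """
    registry = registry or default_registry()
    criteria = set(criteria)
    unknown = criteria - {1, 2, 3}
    if unknown:
        raise ValueError(f"unknown criteria {sorted(unknown)}")
    report = ValidationReport(model_id=model.model_id)

    if 1 in criteria:
        for rule in registry.by_criterion(1):
            report.warnings.extend(rule.condition(model))

    if 2 in criteria:
        for process in model.iter_processes():
            rule = registry.event_rule(process.biological_event)
            if rule is None:
                report.uncovered_events.add(process.biological_event)
                continue
            report.warnings.extend(rule.condition(model, process.id))

    if 3 in criteria:
        labels = {
            "c3-starting-entity": "starting_entities",
            "c3-starting-complex": "starting_complexes",
            "c3-degrading-entity": "degrading_entities",
        }
        for rule in registry.by_criterion(3):
            report.complementation_needed[labels[rule.rule_id]] = len(
                rule.condition(model)
            )

    return report.finalize()


def list_rules(
    registry: RuleRegistry | None = None,
    criterion: int | None = None,
    group: int | None = None,
) -> list[dict]:
    """Stable rule catalogue, optionally filtered by criterion and group."""
    registry = registry or default_registry()
    if criterion is not None and criterion not in (1, 2, 3):
        raise ValueError(f"unknown criterion {criterion!r}")
    if group is not None and group not in (1, 2, 3, 4, 5):
        raise ValueError(f"unknown group {group!r}")
    rows = [
        r.summary()
        for r in sorted(registry.rules,
                        key=lambda r: (r.criterion, r.group or 0, r.rule_id))
        if (criterion is None or r.criterion == criterion)
        and (group is None or r.group == group)
    ]
    return rows


def uncovered_events(
    model: PathwayModel, registry: RuleRegistry | None = None
) -> set[str]:
    """Event terms appearing on processes with no matching criterion-2 rule."""
    registry = registry or default_registry()
    covered = {r.trigger_event for r in registry.by_criterion(2)}
    return {
        p.biological_event
        for p in model.processes.values()
        if p.biological_event not in covered
    }
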