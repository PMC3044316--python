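"""Warning taxonomy and the validation report.

Each detected violation becomes one :class:`Warning` carrying a single
category. Categories keep the wrong/not-defined distinction of curated-model
QC reports: a wrongly valued property and an absent property point to
different curation mistakes.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field


class WarningCategory(str, enum.Enum):
    # cardinality constraint
    WRONG_CARDINALITY_INPUT = "WRONG_CARDINALITY_INPUT"
    WRONG_CARDINALITY_INPUTPROCESS = "WRONG_CARDINALITY_INPUTPROCESS"
    WRONG_CARDINALITY_OUTPUT = "WRONG_CARDINALITY_OUTPUT"
    MISSING_INPUTPROCESS = "MISSING_INPUTPROCESS"
    MISSING_OUTPUT = "MISSING_OUTPUT"
    # type constraint
    WRONG_TYPE = "WRONG_TYPE"
    MISSING_TYPE = "MISSING_TYPE"
    # property constraint
    WRONG_CELLCOMPONENT = "WRONG_CELLCOMPONENT"
    MISSING_CELLCOMPONENT = "MISSING_CELLCOMPONENT"
    MISSING_FEATURETYPE = "MISSING_FEATURETYPE"
    WRONG_STOICHIOMETRY = "WRONG_STOICHIOMETRY"
    MISSING_UNIFICATIONXREF = "MISSING_UNIFICATIONXREF"
    WRONG_UNIFICATIONXREF = "WRONG_UNIFICATIONXREF"
    # property relationship constraint
    SAME_CELLCOMPONENT_SHOULD_DIFFER = "SAME_CELLCOMPONENT_SHOULD_DIFFER"
    # structural (valid-connection) check
    INVALID_CONNECTION = "INVALID_CONNECTION"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Warning:
    """One violated constraint clause on one process (or entity pair).

    Several offending entities of the same clause are listed together in
    ``entity_ids`` rather than fanned out into separate warnings. The
    message is a deterministic function of the other fields.
    """

    category: WarningCategory
    rule_id: str
    message: str
    process_id: str | None = None
    entity_ids: tuple[str, ...] = ()
    event_term: str | None = None

    def sort_key(self) -> tuple:
        return (
            self.process_id or "",
            self.rule_id,
            self.category.value,
            self.entity_ids,
        )

    def to_json(self) -> dict:
        return {
            "category": self.category.value,
            "rule_id": self.rule_id,
            "process_id": self.process_id,
            "entity_ids": list(self.entity_ids),
            "event_term": self.event_term,
            "message": self.message,
        }


@dataclass
class ValidationReport:
    """Ordered warning list plus exact marginal counts.

    ``counts_by_event`` marginalizes warnings over (event term, category) —
    the shape in which curation feedback is usually summarized (which
    events attract which mistakes). ``uncovered_events`` is a side channel:
    event terms on processes for which no rule exists are not warnings.
    ``complementation_needed`` reports how many species a complementation
    pass would touch (populated only when criterion 3 is requested).
    """

    model_id: str
    warnings: list[Warning] = field(default_factory=list)
    uncovered_events: set[str] = field(default_factory=set)
    complementation_needed: dict[str, int] = field(default_factory=dict)

    def finalize(self) -> "ValidationReport":
        self.warnings.sort(key=Warning.sort_key)
        return self

    @property
    def counts_by_category(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for w in self.warnings:
            out[w.category.value] = out.get(w.category.value, 0) + 1
        return out

    @property
    def counts_by_event(self) -> dict[tuple[str, str], int]:
        out: dict[tuple[str, str], int] = {}
        for w in self.warnings:
            key = (w.event_term or "-", w.category.value)
            out[key] = out.get(key, 0) + 1
        return out

    def to_json(self) -> str:
        doc = {
            "model_id": self.model_id,
            "n_warnings": len(self.warnings),
            "warnings": [w.to_json() for w in self.warnings],
            "counts_by_category": dict(sorted(self.counts_by_category.items())),
            "counts_by_event": [
                {"event": ev, "category": cat, "count": n}
                for (ev, cat), n in sorted(self.counts_by_event.items())
            ],
            "uncovered_events": sorted(self.uncovered_events),
            "complementation_needed": dict(
                sorted(self.complementation_needed.items())
            ),
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"

    def to_tsv(self, event_frequencies: dict[str, int] | None = None) -> str:
        """Per-event summary table: event, frequency in model, warning count,
        reasons with per-category counts."""
        freqs = event_frequencies or {}
        per_event: dict[str, dict[str, int]] = {}
        for w in self.warnings:
            ev = w.event_term or "-"
            per_event.setdefault(ev, {})
            per_event[ev][w.category.value] = (
                per_event[ev].get(w.category.value, 0) + 1
            )
        events = sorted(set(per_event) | set(freqs))
        lines = ["event\tfrequency\twarnings\treasons"]
        for ev in events:
            cats = per_event.get(ev, {})
            reasons = ", ".join(f"{c} ({n})" for c, n in sorted(cats.items()))
            lines.append(
                f"{ev}\t{freqs.get(ev, '')}\t{sum(cats.values())}\t{reasons}"
            )
        return "\n".join(lines) + "\n"

    def to_text(self) -> str:
        """Human-readable report, warnings grouped by process then category."""
        if not self.warnings:
            body = "no warnings\n"
        else:
            lines = []
            current = object()
            for w in self.warnings:
                if w.process_id != current:
                    current = w.process_id
                    header = w.process_id or "(model level)"
                    if w.event_term:
                        header += f" [{w.event_term}]"
                    lines.append(f"process {header}:")
                lines.append(f"  {w.category.value}: {w.message}")
            body = "\n".join(lines) + "\n"
        head = f"model {self.model_id}: {len(self.warnings)} warning(s)\n"
        if self.uncovered_events:
            head += (
                "events without rules: "
                + ", ".join(sorted(self.uncovered_events))
                + "\n"
            )
        return head + body
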