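"""Independent brute-force validator used as a test oracle.

Re-checks every process with plain loops over the raw constraint-table
records (no shared code with the clause engine beyond the data file and
the model container). Returns a multiset of (process_id, category-name)
pairs for comparison with the engine's report.
"""

from __future__ import annotations

import json
from collections import Counter
from importlib import resources

from pathwayqc.model import PathwayModel

INPUT_ROLES = {
    "InputProcessBiological", "InputInhibitorBiological",
    "InputAssociationBiological",
}

_CARD_WRONG = {
    "input": "WRONG_CARDINALITY_INPUT",
    "inputprocess": "WRONG_CARDINALITY_INPUTPROCESS",
    "output": "WRONG_CARDINALITY_OUTPUT",
}
_CARD_MISSING = {"inputprocess": "MISSING_INPUTPROCESS",
                 "output": "MISSING_OUTPUT"}


def raw_constraint_table() -> dict[str, dict]:
    text = resources.files("pathwayqc").joinpath(
        "data/constraints.json").read_text()
    doc = json.loads(text)
    return {rec["event"]: rec for rec in doc["constraints"]}


def _is_a(cls: str, required: str) -> bool:
    return cls == required or required == "Entity"


def _xrefs(entity) -> set[tuple[str, str]]:
    return {(x.db.casefold(), x.accession.casefold())
            for x in entity.unification_xrefs}


def naive_check_process(model: PathwayModel, pid: str,
                        rec: dict) -> list[str]:
    """All violated-clause categories for one process, naively."""
    conns = [c for c in model.connectors.values() if c.process_id == pid]
    parts = {
        "input": [(model.entities[c.entity_id], c) for c in conns
                  if c.role.value in INPUT_ROLES],
        "inputprocess": [(model.entities[c.entity_id], c) for c in conns
                         if c.role.value == "InputProcessBiological"],
        "output": [(model.entities[c.entity_id], c) for c in conns
                   if c.role.value == "OutputProcessBiological"],
    }
    cats: list[str] = []
    missing: set[str] = set()

    for spec in rec.get("cardinalities", []):
        role, mn, mx = spec["role"], spec.get("min", 0), spec.get("max")
        n = len(parts[role])
        if n >= mn and (mx is None or n <= mx):
            continue
        if n == 0 and mn >= 1:
            missing.add(role)
            if role in _CARD_MISSING:
                cats.append(_CARD_MISSING[role])
                continue
        cats.append(_CARD_WRONG[role])

    def live(role: str) -> bool:
        return role not in missing and bool(parts[role])

    for spec in rec.get("types", []):
        role = spec["role"]
        if not live(role):
            continue
        ents = [e for e, _ in parts[role]]
        req = spec["class"]
        if spec.get("quantifier", "all") == "all":
            bad = [e for e in ents if not _is_a(e.entity_class.value, req)]
            if bad:
                cats.append("MISSING_TYPE"
                            if all(e.entity_class.value == "Entity" for e in bad)
                            else "WRONG_TYPE")
        else:
            if not any(_is_a(e.entity_class.value, req) for e in ents):
                cats.append("MISSING_TYPE"
                            if all(e.entity_class.value == "Entity"
                                   for e in ents)
                            else "WRONG_TYPE")

    for spec in rec.get("properties", []):
        role = spec["role"]
        if not live(role):
            continue
        pairs = parts[role]
        prop, req = spec["property"], spec["requirement"]
        if prop == "feature_type":
            if not any(spec["value"] in e.feature_types for e, _ in pairs):
                cats.append("MISSING_FEATURETYPE")
        elif prop == "cell_component":
            if any(e.cell_component is None for e, _ in pairs):
                cats.append("MISSING_CELLCOMPONENT")
            if req != "must-be-present":
                allowed = ([spec["value"]] if req == "equals-term"
                           else list(spec["value"]))
                if any(e.cell_component is not None
                       and e.cell_component not in allowed for e, _ in pairs):
                    cats.append("WRONG_CELLCOMPONENT")
        elif prop == "stoichiometry":
            def ok(n):
                if req == "equals-integer":
                    return n == spec["value"]
                lo, hi = spec["value"]
                return n >= lo and (hi is None or n <= hi)
            if any(not ok(c.stoichiometry) for _, c in pairs):
                cats.append("WRONG_STOICHIOMETRY")
        elif prop == "unification_xref":
            if any(not e.unification_xrefs for e, _ in pairs):
                cats.append("MISSING_UNIFICATIONXREF")

    for spec in rec.get("relationships", []):
        ra, rb = spec["role_a"], spec["role_b"]
        if not live(ra) or not live(rb):
            continue
        side_a = [e for e, _ in parts[ra]]
        side_b = [e for e, _ in parts[rb]]
        if spec["property"] == "unification_xref":
            if any(not e.unification_xrefs for e in side_a + side_b):
                cats.append("MISSING_UNIFICATIONXREF")
                continue
            if spec["relation"] == "same":
                if any(all(not (_xrefs(a) & _xrefs(b)) for a in side_a)
                       for b in side_b):
                    cats.append("WRONG_UNIFICATIONXREF")
        else:  # cell_component
            pa = [e for e in side_a if e.cell_component is not None]
            pb = [e for e in side_b if e.cell_component is not None]
            if not pa or not pb:
                continue
            if spec["relation"] == "different":
                if any(a.cell_component == b.cell_component
                       for a in pa for b in pb):
                    cats.append("SAME_CELLCOMPONENT_SHOULD_DIFFER")
            else:
                if any(a.cell_component != b.cell_component
                       for a in pa for b in pb):
                    cats.append("WRONG_CELLCOMPONENT")
    return cats


def naive_validate(model: PathwayModel,
                   table: dict[str, dict] | None = None) -> Counter:
    """Criterion 1 + 2 violation multiset: Counter of (pid, category)."""
    table = table if table is not None else raw_constraint_table()
    out: Counter = Counter()
    pair_counts: Counter = Counter()
    for c in model.connectors.values():
        pair_counts[(c.process_id, c.entity_id)] += 1
    for (pid, _eid), n in pair_counts.items():
        if n >= 2:
            out[(pid, "INVALID_CONNECTION")] += 1
    for pid, proc in model.processes.items():
        rec = table.get(proc.biological_event)
        if rec is None:
            continue
        for cat in naive_check_process(model, pid, rec):
            out[(pid, cat)] += 1
    return out
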