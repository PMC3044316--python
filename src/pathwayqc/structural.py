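"""Structural validation: the valid-connection rule.

One entity may participate in a process with only one role, so a
(process, entity) pair may be joined by at most one connector. Five
configurations are valid for any pair: no connection, or exactly one
connector in one of the four roles. Two or more connectors on a pair —
whatever their roles — is a violation the tool cannot repair on its own:
choosing which connector is right requires understanding the interaction,
so the warning lists every connector of the pair as a fix candidate.
"""

from __future__ import annotations

from .model import PathwayModel
from .report import Warning, WarningCategory

RULE_ID = "c1-valid-connection"

#: no connection plus one per connector role
N_VALID_CONFIGURATIONS = 5


def check_valid_connections(model: PathwayModel) -> list[Warning]:
    """One INVALID_CONNECTION warning per (process, entity) pair joined by
    two or more connectors."""
    pairs: dict[tuple[str, str], list] = {}
    for c in model.connectors.values():
        pairs.setdefault((c.process_id, c.entity_id), []).append(c)
    warnings = []
    for (pid, eid), conns in sorted(pairs.items()):
        if len(conns) <= 1:
            continue
        conns = sorted(conns, key=lambda c: c.id)
        candidates = ", ".join(f"{c.id} ({c.role.value})" for c in conns)
        warnings.append(Warning(
            category=WarningCategory.INVALID_CONNECTION,
            rule_id=RULE_ID,
            message=(
                f"entity {eid} participates in process {pid} through "
                f"{len(conns)} connectors; keep exactly one of: {candidates}"
            ),
            process_id=pid,
            entity_ids=(eid,),
            event_term=model.processes[pid].biological_event
            if pid in model.processes else None,
        ))
    return warnings
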