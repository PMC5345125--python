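"""Rule-based validation of the event/occurrence/eMoF linkage semantics.

The format's promise is referential: every measurement hangs off an event,
biotic measurements additionally off an occurrence, and occurrences off
events.  :func:`validate_bundle` checks the full rule registry below and
always returns a complete report (no fail-fast).  ERROR-severity issues
block conversion and writing; WARNING and INFO do not — that enforcement
split is this package's own convention.

Rule registry
-------------
====  =======  ==========================================================
R1    ERROR    eMoF eventID must exist among the events
R2    ERROR    non-empty eMoF occurrenceID must exist among occurrences
R3    ERROR    occurrence eventID must exist among the events
R4    ERROR    biotic eMoF row's eventID must equal its occurrence's event
R5    ERROR    duplicate eventID or occurrenceID
R6    WARNING  non-empty parentEventID absent from the dataset
R7    WARNING  measurementValueID set although the value is numeric
R8    WARNING  quantification in organismQuantity AND in the eMoF
R9    INFO     measurementType/Unit present without a vocabulary URI
R10   ERROR    parentEventID hierarchy contains a cycle
R11   ERROR    coordinate or depth range violation
====  =======  ==========================================================
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

from .errors import SizeLimitError
from .model import DatasetBundle, is_numeric_literal

__all__ = ["ValidationIssue", "validate_bundle", "oracle_referential_check",
           "RULES", "issues_to_jsonl", "issues_to_text", "has_errors"]

RULES: dict[str, tuple[str, str]] = {
    "R1": ("ERROR", "eMoF eventID not found among events"),
    "R2": ("ERROR", "eMoF occurrenceID not found among occurrences"),
    "R3": ("ERROR", "occurrence eventID not found among events"),
    "R4": ("ERROR", "biotic eMoF eventID differs from its occurrence's"),
    "R5": ("ERROR", "duplicate primary identifier"),
    "R6": ("WARNING", "parentEventID not present in this dataset"),
    "R7": ("WARNING", "measurementValueID set on a numeric value"),
    "R8": ("WARNING", "quantification encoded both in organismQuantity "
                      "and in the eMoF"),
    "R9": ("INFO", "free-text term without a controlled-vocabulary URI"),
    "R10": ("ERROR", "event hierarchy contains a cycle"),
    "R11": ("ERROR", "coordinate or depth out of range"),
}

# measurementTypes treated as organism quantifications for rule R8
_QUANTIFICATION_TYPES = frozenset({
    "abundance", "count", "individual count", "individualcount",
    "density", "biomass", "wet weight biomass", "dry weight biomass",
    "% live cover", "percent cover", "cover",
})


@dataclass(frozen=True)
class ValidationIssue:
    """One rule violation pointing at one record."""

    rule_id: str
    severity: str           # ERROR | WARNING | INFO
    record_kind: str        # event | occurrence | emof | bundle
    record_ref: str         # primary ID, or "row N" for eMoF rows
    message: str


def _issue(rule: str, kind: str, ref: str, message: str) -> ValidationIssue:
    return ValidationIssue(rule, RULES[rule][0], kind, ref, message)


def has_errors(issues: list[ValidationIssue]) -> bool:
    return any(i.severity == "ERROR" for i in issues)


def validate_bundle(bundle: DatasetBundle) -> list[ValidationIssue]:
    """Run every rule; returns all issues in input-record order.

    Read-only: the bundle is never modified.  An empty list means the
    bundle is fully conformant.
    """
    issues: list[ValidationIssue] = []
    event_ids: set[str] = set()
    seen_events: set[str] = set()
    for ev in bundle.events:
        if ev.eventID in seen_events:
            issues.append(_issue("R5", "event", ev.eventID,
                                 f"duplicate eventID {ev.eventID!r}"))
        seen_events.add(ev.eventID)
        event_ids.add(ev.eventID)

    # cycles: follow parent chains over the (possibly duplicated) id map
    parent_of = {ev.eventID: ev.parentEventID for ev in bundle.events}
    on_cycle = _cycle_members(parent_of)

    for ev in bundle.events:
        if ev.parentEventID and ev.parentEventID not in event_ids:
            issues.append(_issue(
                "R6", "event", ev.eventID,
                f"parentEventID {ev.parentEventID!r} not in dataset "
                "(may live in another archive)"))
        if ev.eventID in on_cycle:
            issues.append(_issue("R10", "event", ev.eventID,
                                 "event lies on a parentEventID cycle"))
        lat, lon = ev.decimalLatitude, ev.decimalLongitude
        if lat is not None and not -90.0 <= lat <= 90.0:
            issues.append(_issue("R11", "event", ev.eventID,
                                 f"decimalLatitude {lat} outside [-90, 90]"))
        if lon is not None and not -180.0 <= lon <= 180.0:
            issues.append(_issue(
                "R11", "event", ev.eventID,
                f"decimalLongitude {lon} outside [-180, 180]"))
        lo, hi = ev.minimumDepthInMeters, ev.maximumDepthInMeters
        if lo is not None and hi is not None and lo > hi:
            issues.append(_issue(
                "R11", "event", ev.eventID,
                f"minimumDepthInMeters {lo} > maximumDepthInMeters {hi}"))

    occ_event: dict[str, str] = {}
    seen_occ: set[str] = set()
    emof_by_occ: dict[str, list] = {}
    for m in bundle.measurements:
        if m.occurrenceID:
            emof_by_occ.setdefault(m.occurrenceID, []).append(m)

    for occ in bundle.occurrences:
        if occ.occurrenceID in seen_occ:
            issues.append(_issue(
                "R5", "occurrence", occ.occurrenceID,
                f"duplicate occurrenceID {occ.occurrenceID!r}"))
        seen_occ.add(occ.occurrenceID)
        occ_event.setdefault(occ.occurrenceID, occ.eventID)
        if bundle.events and occ.eventID and occ.eventID not in event_ids:
            issues.append(_issue(
                "R3", "occurrence", occ.occurrenceID,
                f"eventID {occ.eventID!r} not found among events"))
        if occ.organismQuantity is not None:
            for m in emof_by_occ.get(occ.occurrenceID, []):
                mtype = m.measurementType.strip().lower()
                if (mtype in _QUANTIFICATION_TYPES
                        or (occ.organismQuantityType
                            and mtype == occ.organismQuantityType
                            .strip().lower())):
                    issues.append(_issue(
                        "R8", "occurrence", occ.occurrenceID,
                        "organismQuantity duplicates eMoF "
                        f"{m.measurementType!r} row"))
                    break

    for row, m in enumerate(bundle.measurements, start=1):
        ref = m.measurementID or f"row {row}"
        if bundle.events and m.eventID and m.eventID not in event_ids:
            issues.append(_issue(
                "R1", "emof", ref,
                f"eventID {m.eventID!r} not found among events"))
        if m.occurrenceID and m.occurrenceID not in occ_event:
            issues.append(_issue(
                "R2", "emof", ref,
                f"occurrenceID {m.occurrenceID!r} not found among "
                "occurrences"))
        elif (m.occurrenceID and m.eventID
                and occ_event[m.occurrenceID]
                and m.eventID != occ_event[m.occurrenceID]):
            issues.append(_issue(
                "R4", "emof", ref,
                f"eventID {m.eventID!r} differs from occurrence "
                f"{m.occurrenceID!r}'s event "
                f"{occ_event[m.occurrenceID]!r}"))
        if m.measurementValueID and is_numeric_literal(m.measurementValue):
            issues.append(_issue(
                "R7", "emof", ref,
                "measurementValueID has no meaning for the numeric value "
                f"{m.measurementValue!r} and should remain empty"))
        if m.measurementType and not m.measurementTypeID:
            issues.append(_issue(
                "R9", "emof", ref,
                f"measurementType {m.measurementType!r} has no "
                "measurementTypeID URI"))
        if m.measurementUnit and not m.measurementUnitID:
            issues.append(_issue(
                "R9", "emof", ref,
                f"measurementUnit {m.measurementUnit!r} has no "
                "measurementUnitID URI"))
    return issues


def _cycle_members(parent_of: dict[str, str]) -> set[str]:
    """Event IDs lying on a parentEventID cycle (naive chain walking)."""
    members: set[str] = set()
    for start in parent_of:
        seen: list[str] = []
        eid = start
        while eid in parent_of and eid not in seen:
            seen.append(eid)
            eid = parent_of[eid]
        if eid in seen:  # walked back onto the chain: cycle from eid on
            members.update(seen[seen.index(eid):])
    return members


def oracle_referential_check(bundle: DatasetBundle) -> list[ValidationIssue]:
    """Brute-force re-implementation of rules R1–R5 by nested list scans.

    Deliberately index-free and quadratic, as an independent oracle for
    equivalence testing against :func:`validate_bundle` on small bundles.
    """
    n = (len(bundle.events) + len(bundle.occurrences)
         + len(bundle.measurements))
    if n > 10_000:
        raise SizeLimitError(f"oracle limited to 1e4 records, got {n}")
    issues: list[ValidationIssue] = []

    for i, ev in enumerate(bundle.events):
        if any(other.eventID == ev.eventID for other in bundle.events[:i]):
            issues.append(_issue("R5", "event", ev.eventID,
                                 f"duplicate eventID {ev.eventID!r}"))

    for i, occ in enumerate(bundle.occurrences):
        if any(o.occurrenceID == occ.occurrenceID
               for o in bundle.occurrences[:i]):
            issues.append(_issue(
                "R5", "occurrence", occ.occurrenceID,
                f"duplicate occurrenceID {occ.occurrenceID!r}"))
        if (bundle.events and occ.eventID
                and not any(ev.eventID == occ.eventID
                            for ev in bundle.events)):
            issues.append(_issue(
                "R3", "occurrence", occ.occurrenceID,
                f"eventID {occ.eventID!r} not found among events"))

    for row, m in enumerate(bundle.measurements, start=1):
        ref = m.measurementID or f"row {row}"
        if (bundle.events and m.eventID
                and not any(ev.eventID == m.eventID
                            for ev in bundle.events)):
            issues.append(_issue(
                "R1", "emof", ref,
                f"eventID {m.eventID!r} not found among events"))
        if m.occurrenceID:
            matches = [o for o in bundle.occurrences
                       if o.occurrenceID == m.occurrenceID]
            if not matches:
                issues.append(_issue(
                    "R2", "emof", ref,
                    f"occurrenceID {m.occurrenceID!r} not found among "
                    "occurrences"))
            elif (m.eventID and matches[0].eventID
                    and matches[0].eventID != m.eventID):
                issues.append(_issue(
                    "R4", "emof", ref,
                    f"eventID {m.eventID!r} differs from occurrence "
                    f"{m.occurrenceID!r}'s event "
                    f"{matches[0].eventID!r}"))
    return issues


def issues_to_jsonl(issues: list[ValidationIssue]) -> str:
    """One JSON object per line; empty string for a clean report."""
    return "\n".join(json.dumps(asdict(i), sort_keys=True) for i in issues)


def issues_to_text(issues: list[ValidationIssue]) -> str:
    if not issues:
        return "no issues found"
    lines = [f"{i.severity:<7} {i.rule_id:<4} {i.record_kind} "
             f"{i.record_ref}: {i.message}" for i in issues]
    counts: dict[str, int] = {}
    for i in issues:
        counts[i.severity] = counts.get(i.severity, 0) + 1
    summary = ", ".join(f"{v} {k}" for k, v in sorted(counts.items()))
    return "\n".join(lines + [f"-- {summary}"])
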