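"""Detecting and converting between candidate archive layouts.

Several layouts can hold combined biological and environmental data in a
Darwin Core Archive:

1. Occurrence core + measurements: every abiotic measurement is duplicated
   onto each occurrence of the same sample, and a sample without organisms
   cannot be stored at all.
2. Event core + occurrence extension + classic MeasurementOrFact: the
   measurement table has no occurrenceID column, so biotic measurements
   cannot be attached to an organism.
4. Occurrence core in which each sampling event is itself an occurrence row
   (``type="event"``, no scientificName) that the measurements hang off.
5. Event core in which every occurrence is wrapped in a one-to-one "dummy"
   event so that biotic measurements can link to it.
6. Event core + occurrence extension + eMoF with an occurrenceID column —
   the recommended layout: biotic rows link to both an event and an
   occurrence, abiotic rows to the event only.

Layouts 2, 4 and 5 are detected and read; 1 and 5 convert to 6 (and 6 back
to 1/4); 2 imports as 6 with an empty occurrenceID column.  Layout 3
(content split over two linked archives) is detect-out-of-scope entirely.
:func:`flatten` denormalizes a clean layout-6 bundle into one analysis-ready
row per measurement with inherited event metadata resolved.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

from .errors import (AmbiguousDummyError, OptionMismatchError,
                     OrphanEventError, ValidationFailedError)
from .hierarchy import (DEFAULT_INHERIT_FIELDS, EventTree, build_tree,
                        hierarchical_id, resolve_inherited,
                        resolve_inherited_coordinates)
from .model import (DatasetBundle, EMOF_FIELDS, EMoFRecord, EventRecord,
                    OccurrenceRecord, get_field, set_field)
from .validation import has_errors, validate_bundle

__all__ = ["detect_option", "option1_to_option6", "option6_to_option1",
           "option5_to_option6", "flatten", "FlatRow", "flat_table",
           "DEFAULT_EVENT_KEY_FIELDS", "FLAT_COLUMNS"]

#: Fields whose value tuple delimits one sampling event when rebuilding
#: events from occurrence-only data (the properties that distinguish
#: samples: when, where, how deep).
DEFAULT_EVENT_KEY_FIELDS = ("eventDate", "decimalLatitude",
                            "decimalLongitude", "minimumDepthInMeters",
                            "maximumDepthInMeters")

# eMoF content signature: everything except the linkage/identity columns
_SIGNATURE_FIELDS = tuple(f for f in EMOF_FIELDS
                          if f not in ("eventID", "occurrenceID",
                                       "measurementID"))


def _signature(m: EMoFRecord) -> tuple[str, ...]:
    return tuple(getattr(m, f) for f in _SIGNATURE_FIELDS)


def detect_option(bundle: DatasetBundle) -> int | str:
    """Classify a bundle's layout from its content (``"unknown"`` when
    unclassifiable)."""
    if not bundle.events:
        if not bundle.occurrences:
            return "unknown"
        if any(get_field(o, "type") == "event" and not o.scientificName
               for o in bundle.occurrences):
            return 4
        return 1
    if bundle.emof_has_occurrence_id or any(m.occurrenceID
                                            for m in bundle.measurements):
        return 6
    if _dummy_wrappers(bundle):
        return 5
    return 2


def _dummy_wrappers(bundle: DatasetBundle) -> list[str]:
    """eventIDs acting as one-to-one dummy wrappers of occurrences."""
    occ_count: dict[str, int] = {}
    for occ in bundle.occurrences:
        occ_count[occ.eventID] = occ_count.get(occ.eventID, 0) + 1
    has_children = {ev.parentEventID for ev in bundle.events
                    if ev.parentEventID}
    return [ev.eventID for ev in bundle.events
            if ev.parentEventID
            and ev.eventID not in has_children
            and occ_count.get(ev.eventID, 0) == 1]


def option1_to_option6(bundle: DatasetBundle,
                       event_key_fields: tuple[str, ...] | None = None
                       ) -> DatasetBundle:
    """Rebuild sampling events from occurrence-only data.

    Occurrences sharing one value tuple over *event_key_fields* are grouped
    into one generated event (``sample1``, ``sample2``, ... in first-
    appearance order — deterministic, content-only).  Measurement rows whose
    full content (ignoring identifiers) repeats identically across every
    occurrence of an event collapse to a single event-level row: the inverse
    of the duplication layout 1 forces.  Rows specific to one occurrence
    keep their occurrenceID.
    """
    if detect_option(bundle) != 1:
        raise OptionMismatchError("bundle is not in layout 1")
    keys = tuple(event_key_fields or DEFAULT_EVENT_KEY_FIELDS)

    groups: dict[tuple[str, ...], list[OccurrenceRecord]] = {}
    for occ in bundle.occurrences:
        groups.setdefault(tuple(get_field(occ, k) for k in keys),
                          []).append(occ)

    out = DatasetBundle(metadata=replace(bundle.metadata),
                        schema_option=6, emof_has_occurrence_id=True)
    rows_by_occ: dict[str, list[EMoFRecord]] = {}
    for m in bundle.measurements:
        rows_by_occ.setdefault(m.occurrenceID, []).append(m)

    for i, (key, occs) in enumerate(groups.items(), start=1):
        event_id = hierarchical_id([f"sample{i}"])
        event = EventRecord(eventID=event_id, type="sample")
        for k, value in zip(keys, key):
            if value != "":
                set_field(event, k, value)
        out.events.append(event)

        for occ in occs:
            new_occ = replace(occ, eventID=event_id,
                              extras={k: v for k, v in occ.extras.items()
                                      if k not in keys})
            out.occurrences.append(new_occ)

        # collapse layers of measurements shared by every occurrence
        remaining = {occ.occurrenceID:
                     list(rows_by_occ.get(occ.occurrenceID, []))
                     for occ in occs}
        if len(occs) >= 2:
            first = occs[0].occurrenceID
            for row in list(remaining[first]):
                sig = _signature(row)
                layer = [row]
                for occ in occs[1:]:
                    match = next((r for r in remaining[occ.occurrenceID]
                                  if _signature(r) == sig), None)
                    if match is None:
                        break
                    layer.append(match)
                if len(layer) == len(occs):
                    for occ, r in zip(occs, layer):
                        remaining[occ.occurrenceID].remove(r)
                    out.measurements.append(replace(
                        row, eventID=event_id, occurrenceID=""))
        for occ in occs:
            for row in remaining[occ.occurrenceID]:
                out.measurements.append(replace(row, eventID=event_id))
    return out


def _tolerant_tree(events: list[EventRecord]) -> EventTree:
    """Build the tree treating cross-archive parents as roots."""
    ids = {ev.eventID for ev in events}
    adjusted = [replace(ev, parentEventID=ev.parentEventID
                        if ev.parentEventID in ids else "")
                for ev in events]
    return build_tree(adjusted)


def _subtree_ids(tree: EventTree, root: str) -> list[str]:
    out, stack = [], [root]
    while stack:
        eid = stack.pop()
        out.append(eid)
        stack.extend(reversed(tree.children.get(eid, [])))
    return out


def option6_to_option1(bundle: DatasetBundle,
                       allow_event_records: bool = False) -> DatasetBundle:
    """Dissolve the event structure into an occurrence-core layout.

    Event-level measurements are duplicated onto every occurrence of the
    event's subtree, and the event metadata the occurrences would otherwise
    inherit (date, coordinates, footprint, the event's own depth range) is
    materialized onto each occurrence record — the redundancy layout 1
    forces.  An event whose subtree holds measurements but no occurrence
    cannot be represented unless *allow_event_records* is set, in which
    case a layout-4-style occurrence row with ``type="event"`` is emitted.
    """
    if detect_option(bundle) != 6:
        raise OptionMismatchError("bundle is not in layout 6")
    tree = _tolerant_tree(bundle.events)

    occs_by_event: dict[str, list[OccurrenceRecord]] = {}
    for occ in bundle.occurrences:
        occs_by_event.setdefault(occ.eventID, []).append(occ)

    out = DatasetBundle(metadata=replace(bundle.metadata),
                        emof_has_occurrence_id=True)

    def materialize(occ: OccurrenceRecord,
                    event_id: str) -> OccurrenceRecord:
        new = replace(occ, eventID="", extras=dict(occ.extras))
        lat, lon = resolve_inherited_coordinates(tree, event_id)
        values = {"decimalLatitude": lat, "decimalLongitude": lon}
        for f in ("eventDate", "footprintWKT"):
            values[f] = resolve_inherited(tree, event_id, f)
        for f in ("minimumDepthInMeters", "maximumDepthInMeters"):
            values[f] = get_field(tree.nodes[event_id], f)  # never inherited
        for f, v in values.items():
            if v != "":
                new.extras[f] = v
        return new

    emitted: dict[str, OccurrenceRecord] = {}
    for occ in bundle.occurrences:
        new = materialize(occ, occ.eventID) if occ.eventID in tree.nodes \
            else replace(occ, eventID="", extras=dict(occ.extras))
        emitted[occ.occurrenceID] = new
        out.occurrences.append(new)

    event_rows: dict[str, list[EMoFRecord]] = {}
    occ_rows: list[EMoFRecord] = []
    for m in bundle.measurements:
        if m.occurrenceID:
            occ_rows.append(replace(m, eventID=""))
        else:
            event_rows.setdefault(m.eventID, []).append(m)

    for ev in bundle.events:
        rows = event_rows.get(ev.eventID, [])
        if not rows:
            continue
        targets = [occ for eid in _subtree_ids(tree, ev.eventID)
                   for occ in occs_by_event.get(eid, [])]
        if targets:
            for row in rows:
                for occ in targets:
                    out.measurements.append(replace(
                        row, eventID="", occurrenceID=occ.occurrenceID))
        elif allow_event_records:
            record = OccurrenceRecord(
                occurrenceID=ev.eventID, eventID=ev.eventID,
                extras={"type": "event"})
            if ev.parentEventID:
                record.extras["parentEventID"] = ev.parentEventID
            record = replace(materialize(record, ev.eventID),
                             eventID=ev.eventID)
            out.occurrences.append(record)
            for row in rows:
                out.measurements.append(replace(
                    row, eventID="", occurrenceID=ev.eventID))
        else:
            raise OrphanEventError(
                f"event {ev.eventID!r} has measurements but no occurrence "
                "in its subtree; layout 1 cannot store abiotic data "
                "without biotic data (pass allow_event_records for a "
                "layout-4 event record)")
    out.measurements.extend(occ_rows)
    out.schema_option = detect_option(out)
    return out


def option5_to_option6(bundle: DatasetBundle) -> DatasetBundle:
    """Unwrap one-to-one dummy events into direct occurrence links.

    Each dummy (a childless event wrapping exactly one occurrence) is
    deleted; its occurrence is re-linked to the dummy's parent event, and
    measurements that hung on the dummy become biotic rows carrying the
    occurrence's occurrenceID.  A bundle without dummies is returned
    unchanged.
    """
    detected = detect_option(bundle)
    if detected in (2, 6):
        return copy.deepcopy(bundle)
    if detected != 5:
        raise OptionMismatchError(f"bundle is in layout {detected!r}")

    occ_by_event: dict[str, list[OccurrenceRecord]] = {}
    for occ in bundle.occurrences:
        occ_by_event.setdefault(occ.eventID, []).append(occ)
    has_children = {ev.parentEventID for ev in bundle.events
                    if ev.parentEventID}

    dummies: dict[str, tuple[str, str]] = {}  # dummy -> (parent, occID)
    for ev in bundle.events:
        if (ev.parentEventID and ev.eventID not in has_children
                and ev.eventID in occ_by_event):
            wrapped = occ_by_event[ev.eventID]
            if len(wrapped) > 1:
                raise AmbiguousDummyError(
                    f"dummy event {ev.eventID!r} wraps "
                    f"{len(wrapped)} occurrences")
            dummies[ev.eventID] = (ev.parentEventID,
                                   wrapped[0].occurrenceID)

    out = DatasetBundle(metadata=replace(bundle.metadata),
                        schema_option=6, emof_has_occurrence_id=True)
    out.events = [replace(ev) for ev in bundle.events
                  if ev.eventID not in dummies]
    out.occurrences = [
        replace(occ, eventID=dummies[occ.eventID][0],
                extras=dict(occ.extras))
        if occ.eventID in dummies else replace(occ, extras=dict(occ.extras))
        for occ in bundle.occurrences]
    out.measurements = [
        replace(m, eventID=dummies[m.eventID][0],
                occurrenceID=dummies[m.eventID][1])
        if m.eventID in dummies else replace(m)
        for m in bundle.measurements]
    return out


@dataclass(frozen=True)
class FlatRow:
    """One denormalized measurement row for analysis or export."""

    event_path: tuple[str, ...]   # eventIDs from root down to the event
    eventDate: str
    decimalLatitude: str
    decimalLongitude: str
    footprintWKT: str
    occurrenceID: str
    scientificName: str
    measurement: EMoFRecord


def flatten(bundle: DatasetBundle,
            inherit_fields: tuple[str, ...] = DEFAULT_INHERIT_FIELDS
            ) -> list[FlatRow]:
    """One :class:`FlatRow` per eMoF record, with event metadata resolved
    through the hierarchy for the fields in *inherit_fields* (coordinates
    always as a pair from a single ancestor; depths never inherit).

    Requires a layout-6 bundle free of ERROR issues; raises
    :class:`ValidationFailedError` otherwise.  Rows come back ordered by
    event path, then occurrenceID.
    """
    issues = validate_bundle(bundle)
    blocking = [i for i in issues if i.severity == "ERROR"]
    if blocking:
        raise ValidationFailedError(blocking)
    if detect_option(bundle) not in (2, 6):
        raise OptionMismatchError("flatten requires an event-core bundle")
    tree = _tolerant_tree(bundle.events)
    occ_by_id = {o.occurrenceID: o for o in bundle.occurrences}

    rows: list[FlatRow] = []
    for m in bundle.measurements:
        path = (tuple(tree.path_to_root(m.eventID))
                if m.eventID in tree.nodes else (m.eventID,))
        values = {f: "" for f in ("eventDate", "decimalLatitude",
                                  "decimalLongitude", "footprintWKT")}
        if m.eventID in tree.nodes:
            node = tree.nodes[m.eventID]
            if ("decimalLatitude" in inherit_fields
                    or "decimalLongitude" in inherit_fields):
                lat, lon = resolve_inherited_coordinates(tree, m.eventID)
                values["decimalLatitude"] = lat
                values["decimalLongitude"] = lon
            for f in ("eventDate", "footprintWKT"):
                values[f] = (resolve_inherited(tree, m.eventID, f)
                             if f in inherit_fields else get_field(node, f))
        occ = occ_by_id.get(m.occurrenceID)
        rows.append(FlatRow(
            event_path=path,
            occurrenceID=m.occurrenceID,
            scientificName=occ.scientificName if occ else "",
            measurement=replace(m),
            **values))
    rows.sort(key=lambda r: (r.event_path, r.occurrenceID))
    return rows


#: Column order of the flat-table export (fixed).
FLAT_COLUMNS = (("eventPath", "eventDate", "decimalLatitude",
                 "decimalLongitude", "footprintWKT", "scientificName")
                + EMOF_FIELDS)


def flat_table(rows: list[FlatRow]) -> str:
    """Tab-separated export of flattened rows, one header line."""
    lines = ["\t".join(FLAT_COLUMNS)]
    for r in rows:
        head = [" > ".join(r.event_path), r.eventDate, r.decimalLatitude,
                r.decimalLongitude, r.footprintWKT, r.scientificName]
        lines.append("\t".join(head + [getattr(r.measurement, f)
                                       for f in EMOF_FIELDS]))
    return "\n".join(lines) + "\n"
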