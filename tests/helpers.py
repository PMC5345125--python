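"""Shared builders for randomized test bundles (seeded, deterministic)."""

from __future__ import annotations

import random

from obisenv.model import (DatasetBundle, EMoFRecord, EventRecord,
                           OccurrenceRecord)

TAXA = ("Abra alba", "Nephtys hombergii", "Calanus finmarchicus",
        "Oithona similis", "Lanice conchilega")


def random_option6_instance(rng: random.Random,
                            max_events: int = 4,
                            max_occ: int = 5,
                            max_abiotic: int = 4) -> DatasetBundle:
    """Flat layout-6 bundle: events with distinct when/where keys, n>=1
    occurrences each, m>=1 distinct event-level (abiotic) rows each, and
    one distinct biotic row per occurrence."""
    bundle = DatasetBundle(schema_option=6)
    n_events = rng.randint(1, max_events)
    occ_counter = 0
    for e in range(n_events):
        eid = f"ev{e}"
        bundle.events.append(EventRecord(
            eventID=eid, eventDate=f"2016-03-{e + 1:02d}",
            decimalLatitude=round(50.0 + e * 0.5, 3),
            decimalLongitude=round(3.0 + e * 0.25, 3)))
        n = rng.randint(1, max_occ)
        m = rng.randint(1, max_abiotic)
        occs = []
        for _ in range(n):
            occ_counter += 1
            occ = OccurrenceRecord(f"occ{occ_counter}", eventID=eid,
                                   scientificName=rng.choice(TAXA))
            occs.append(occ)
            bundle.occurrences.append(occ)
        for j in range(m):
            bundle.measurements.append(EMoFRecord(
                eventID=eid, measurementType=f"abiotic{j}",
                measurementValue=f"{rng.uniform(1, 30):.2f}",
                measurementUnit="degC"))
        for k, occ in enumerate(occs):
            bundle.measurements.append(EMoFRecord(
                eventID=eid, occurrenceID=occ.occurrenceID,
                measurementType="Body length",
                measurementValue=f"{10 + k}.{rng.randint(0, 9)}",
                measurementUnit="cm"))
    return bundle


def random_bundle_with_defects(rng: random.Random) -> DatasetBundle:
    """Random bundle with referential defects injected at known rates:
    dangling links (R1-R3), event mismatches (R4), duplicate IDs (R5)."""
    bundle = random_option6_instance(rng)
    if rng.random() < 0.4 and bundle.events:
        bundle.events.append(EventRecord(
            eventID=rng.choice(bundle.events).eventID))  # R5 duplicate
    if rng.random() < 0.4 and bundle.occurrences:
        victim = rng.choice(bundle.occurrences)
        bundle.occurrences.append(OccurrenceRecord(
            occurrenceID=victim.occurrenceID, eventID=victim.eventID))
    if rng.random() < 0.5:
        bundle.occurrences.append(OccurrenceRecord(
            f"ghostocc{rng.randint(0, 99)}", eventID="no-such-event"))  # R3
    if rng.random() < 0.5:
        bundle.measurements.append(EMoFRecord(
            eventID="no-such-event", measurementType="stray",
            measurementValue="1"))  # R1
    if rng.random() < 0.5:
        bundle.measurements.append(EMoFRecord(
            eventID=bundle.events[0].eventID,
            occurrenceID="no-such-occurrence",
            measurementType="stray biotic", measurementValue="2"))  # R2
    if rng.random() < 0.5 and len(bundle.events) > 1:
        occ = rng.choice(bundle.occurrences)
        other = next((ev.eventID for ev in bundle.events
                      if ev.eventID != occ.eventID), None)
        if other:
            bundle.measurements.append(EMoFRecord(
                eventID=other, occurrenceID=occ.occurrenceID,
                measurementType="misfiled biotic",
                measurementValue="3"))  # R4
    return bundle


def implied_pairs(bundle: DatasetBundle) -> list[tuple]:
    """The occurrence-measurement multiset a layout implies.

    Occurrence-level rows pair with their occurrence's name; event-level
    rows imply one pair per occurrence of that event (the duplication an
    occurrence-core layout must materialize).  Assumes a flat hierarchy.
    """
    occ_name = {o.occurrenceID: o.scientificName
                for o in bundle.occurrences}
    occs_of = {}
    for o in bundle.occurrences:
        occs_of.setdefault(o.eventID, []).append(o)
    pairs = []
    for m in bundle.measurements:
        sig = (m.measurementType, m.measurementValue, m.measurementUnit)
        if m.occurrenceID:
            pairs.append(sig + (occ_name.get(m.occurrenceID, ""),))
        elif m.eventID and m.eventID in occs_of:
            for o in occs_of[m.eventID]:
                pairs.append(sig + (o.scientificName,))
        else:  # occurrence-core layouts: event-level rows do not exist
            pairs.append(sig + ("",))
    return sorted(pairs)
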