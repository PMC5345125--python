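"""Layout detection, conversions between layouts, and flattening."""

import random

import pytest

from helpers import implied_pairs, random_option6_instance
from obisenv import fixtures
from obisenv.errors import (AmbiguousDummyError, OptionMismatchError,
                            OrphanEventError, ValidationFailedError)
from obisenv.model import (DatasetBundle, EMoFRecord, EventRecord,
                           OccurrenceRecord)
from obisenv.options import (detect_option, flat_table, flatten,
                             option1_to_option6, option5_to_option6,
                             option6_to_option1)


def _option1_instance(n_samples=2, n_occ=2, n_shared=1):
    """Occurrence-core bundle where each sample's shared measurements are
    duplicated onto every occurrence — the layout-1 redundancy."""
    bundle = DatasetBundle(schema_option=1)
    counter = 0
    for s in range(n_samples):
        key = {"eventDate": f"2016-06-{s + 1:02d}",
               "decimalLatitude": f"{51 + s}.5",
               "decimalLongitude": "2.5"}
        for o in range(n_occ):
            counter += 1
            occ = OccurrenceRecord(f"o{counter}",
                                   scientificName=f"Taxon {o}",
                                   extras=dict(key))
            bundle.occurrences.append(occ)
            for m in range(n_shared):
                bundle.measurements.append(EMoFRecord(
                    occurrenceID=occ.occurrenceID,
                    measurementType=f"shared{m}",
                    measurementValue=f"{12 + m}.5",
                    measurementUnit="degC"))
            bundle.measurements.append(EMoFRecord(
                occurrenceID=occ.occurrenceID,
                measurementType="Body length",
                measurementValue=f"{o + 1}.{s}", measurementUnit="cm"))
    return bundle


class TestDetect:
    def test_generated_fixtures_are_layout6(self, category_bundle):
        assert detect_option(category_bundle) == 6

    def test_occurrence_only_bundle_is_layout1(self):
        assert detect_option(_option1_instance()) == 1

    def test_empty_bundle_unknown(self):
        assert detect_option(DatasetBundle()) == "unknown"

    def test_event_records_in_occurrence_core_mean_layout4(self):
        bundle = _option1_instance()
        bundle.occurrences.append(OccurrenceRecord(
            "ev-rec", extras={"type": "event"}))
        assert detect_option(bundle) == 4

    def test_event_core_without_occurrence_id_column(self):
        bundle = DatasetBundle(
            events=[EventRecord(eventID="e1")],
            occurrences=[OccurrenceRecord("o1", eventID="e1")],
            measurements=[EMoFRecord(eventID="e1", measurementType="t",
                                     measurementValue="1")],
            emof_has_occurrence_id=False)
        assert detect_option(bundle) == 2


class TestOption1To6:
    def test_shared_measurement_deduplicates(self):
        bundle = _option1_instance(n_samples=1, n_occ=2, n_shared=1)
        out = option1_to_option6(bundle)
        abiotic = [m for m in out.measurements if not m.occurrenceID]
        biotic = [m for m in out.measurements if m.occurrenceID]
        assert len(out.events) == 1
        assert len(out.occurrences) == 2
        assert len(abiotic) == 1 and abiotic[0].measurementType == "shared0"
        assert len(biotic) == 2  # per-organism rows keep their link

    def test_occurrence_specific_row_keeps_its_occurrence(self):
        bundle = _option1_instance(n_samples=1, n_occ=2, n_shared=0)
        out = option1_to_option6(bundle)
        assert all(m.occurrenceID for m in out.measurements)
        assert {m.measurementType for m in out.measurements} == \
            {"Body length"}

    def test_abiotic_rows_drop_from_nm_to_m(self):
        rng = random.Random(7)
        for _ in range(50):
            n, m = rng.randint(2, 5), rng.randint(1, 4)
            bundle = _option1_instance(n_samples=rng.randint(1, 3),
                                       n_occ=n, n_shared=m)
            n_dup = sum(1 for r in bundle.measurements
                        if r.measurementType.startswith("shared"))
            out = option1_to_option6(bundle)
            collapsed = [r for r in out.measurements if not r.occurrenceID]
            assert n_dup == len(out.events) * n * m
            assert len(collapsed) == len(out.events) * m

    def test_generated_event_ids_are_deterministic(self):
        a = option1_to_option6(_option1_instance())
        b = option1_to_option6(_option1_instance())
        assert [e.eventID for e in a.events] == \
            [e.eventID for e in b.events] == ["sample1", "sample2"]

    def test_wrong_layout_rejected(self, category_bundle):
        with pytest.raises(OptionMismatchError):
            option1_to_option6(category_bundle)


class TestOption6To1:
    def test_event_row_duplicates_onto_each_occurrence(self):
        bundle = DatasetBundle(
            events=[EventRecord(eventID="s1", eventDate="2016-06-01")],
            occurrences=[OccurrenceRecord("o1", eventID="s1",
                                          scientificName="A"),
                         OccurrenceRecord("o2", eventID="s1",
                                          scientificName="B")],
            measurements=[EMoFRecord(eventID="s1",
                                     measurementType="Temperature",
                                     measurementValue="12.5",
                                     measurementUnit="degC")])
        out = option6_to_option1(bundle)
        assert len(out.measurements) == 2
        assert {m.occurrenceID for m in out.measurements} == {"o1", "o2"}
        assert all(m.measurementValue == "12.5" for m in out.measurements)
        assert all(o.extras["eventDate"] == "2016-06-01"
                   for o in out.occurrences)

    def test_organism_free_event_needs_the_flag(self):
        bundle = DatasetBundle(
            events=[EventRecord(eventID="s1")],
            measurements=[EMoFRecord(eventID="s1", measurementType="t",
                                     measurementValue="1")])
        with pytest.raises(OrphanEventError):
            option6_to_option1(bundle)
        out = option6_to_option1(bundle, allow_event_records=True)
        assert detect_option(out) == 4
        assert out.occurrences[0].extras["type"] == "event"

    def test_round_trip_conserves_occurrence_measurement_multiset(self):
        """option1 -> option6 -> option1 preserves the flattened
        occurrence-measurement multiset (>=200 random instances)."""
        rng = random.Random(13)
        for _ in range(200):
            bundle = random_option6_instance(rng)
            as1 = option6_to_option1(bundle)
            assert implied_pairs(as1) == implied_pairs(bundle)
            back = option1_to_option6(as1)
            assert implied_pairs(back) == implied_pairs(bundle)

    def test_no_two_identical_event_rows_after_inversion(self):
        rng = random.Random(99)
        for _ in range(50):
            bundle = random_option6_instance(rng)
            back = option1_to_option6(option6_to_option1(bundle))
            for ev in back.events:
                rows = [(m.measurementType, m.measurementValue,
                         m.measurementUnit) for m in back.measurements
                        if m.eventID == ev.eventID and not m.occurrenceID]
                assert len(rows) == len(set(rows))


class TestOption5To6:
    def _dummy_bundle(self):
        return DatasetBundle(
            events=[EventRecord(eventID="s1", type="sample"),
                    EventRecord(eventID="s1:d1", parentEventID="s1"),
                    EventRecord(eventID="s1:d2", parentEventID="s1")],
            occurrences=[OccurrenceRecord("o1", eventID="s1:d1",
                                          scientificName="A"),
                         OccurrenceRecord("o2", eventID="s1:d2",
                                          scientificName="B")],
            measurements=[EMoFRecord(eventID="s1:d1",
                                     measurementType="Wet weight biomass",
                                     measurementValue="3.1",
                                     measurementUnit="g"),
                          EMoFRecord(eventID="s1:d2",
                                     measurementType="Wet weight biomass",
                                     measurementValue="2.7",
                                     measurementUnit="g")],
            emof_has_occurrence_id=False, schema_option=5)

    def test_dummies_unwrap_into_biotic_links(self):
        bundle = self._dummy_bundle()
        assert detect_option(bundle) == 5
        out = option5_to_option6(bundle)
        assert [e.eventID for e in out.events] == ["s1"]
        assert {o.eventID for o in out.occurrences} == {"s1"}
        assert sorted(m.occurrenceID for m in out.measurements) == \
            ["o1", "o2"]
        assert all(m.eventID == "s1" for m in out.measurements)
        assert detect_option(out) == 6

    def test_bundle_without_dummies_is_fixed_point(self, category_bundle):
        out = option5_to_option6(category_bundle)
        assert out == category_bundle

    def test_dummy_wrapping_two_occurrences_is_ambiguous(self):
        bundle = self._dummy_bundle()
        bundle.occurrences.append(OccurrenceRecord("o3", eventID="s1:d1",
                                                   scientificName="C"))
        with pytest.raises(AmbiguousDummyError):
            option5_to_option6(bundle)


class TestFlatten:
    def test_one_row_per_measurement(self, category_bundle):
        rows = flatten(category_bundle)
        assert len(rows) == len(category_bundle.measurements)

    def test_no_measurements_no_rows(self):
        bundle = DatasetBundle(events=[EventRecord(eventID="e")])
        assert flatten(bundle) == []

    def test_position_rows_carry_their_own_coordinates(self):
        """Telemetry: each position-event measurement resolves to that
        position's coordinates, not the track's; biometric rows carry the
        capture occurrence."""
        bundle = fixtures.generate(fixtures.ScenarioSpec(
            category="telemetry", seed=3, sections=2, positions=4))
        rows = flatten(bundle)
        by_leaf = {}
        for r in rows:
            by_leaf.setdefault(r.event_path[-1], []).append(r)
        positions = {e.eventID: e for e in bundle.events
                     if "position" in e.eventID}
        assert positions
        for eid, ev in positions.items():
            for r in by_leaf.get(eid, []):
                assert float(r.decimalLatitude) == ev.decimalLatitude
                assert r.occurrenceID == ""
        biometric = [r for r in rows
                     if r.measurement.measurementType == "Body length"]
        assert biometric and all(r.occurrenceID and r.scientificName
                                 for r in biometric)

    def test_blocking_issues_refuse_flatten(self):
        bundle = DatasetBundle(
            events=[EventRecord(eventID="e")],
            measurements=[EMoFRecord(eventID="ghost",
                                     measurementType="t",
                                     measurementValue="1")])
        with pytest.raises(ValidationFailedError):
            flatten(bundle)

    def test_flat_table_is_rectangular_tsv(self, category_bundle):
        text = flat_table(flatten(category_bundle))
        lines = text.strip("\n").split("\n")
        width = len(lines[0].split("\t"))
        assert all(len(line.split("\t")) == width for line in lines)
        assert len(lines) == len(category_bundle.measurements) + 1
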