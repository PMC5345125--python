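"""Structure and determinism of the synthetic dataset generators."""

import pytest

from obisenv import archive, fixtures, validation
from obisenv.errors import InvalidSpecError
from obisenv.fixtures import ScenarioSpec, generate, registry


class TestDeterminism:
    def test_same_spec_same_bundle(self, category_bundle):
        pass  # fixture itself asserts generatability; equality below

    @pytest.mark.parametrize("category", fixtures.CATEGORIES)
    def test_identical_spec_gives_identical_archive_bytes(self, category,
                                                          tmp_path):
        spec = ScenarioSpec(category=category, seed=42)
        p1 = archive.write_archive(generate(spec), tmp_path / "a.zip")
        p2 = archive.write_archive(generate(spec), tmp_path / "b.zip")
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seeds_differ(self):
        a = generate(ScenarioSpec(category="ctd", seed=1))
        b = generate(ScenarioSpec(category="ctd", seed=2))
        assert a != b


class TestSampleBased:
    def test_zero_stations_leaves_only_the_cruise(self):
        bundle = generate(ScenarioSpec(category="sample_based", seed=1,
                                       stations=0))
        assert [e.type for e in bundle.events] == ["cruise"]
        assert not bundle.occurrences

    def test_trawl_is_a_line_among_point_siblings(self, fig1_bundle):
        trawl = next(e for e in fig1_bundle.events
                     if "trawl" in e.eventID)
        assert trawl.footprintWKT.startswith("LINESTRING")
        grab = next(e for e in fig1_bundle.events if "grab" in e.eventID)
        assert grab.decimalLatitude is not None
        assert grab.footprintWKT == ""

    def test_subsample_slices_carry_meiofauna(self, fig1_bundle):
        slices = [e.eventID for e in fig1_bundle.events
                  if e.type == "subsample"]
        assert slices
        assert any(o.eventID in slices for o in fig1_bundle.occurrences)


class TestCtd:
    def test_child_event_count_is_depths_plus_niskins(self):
        bundle = generate(ScenarioSpec(category="ctd", seed=1,
                                       depths=100, niskins=3))
        cast = next(e for e in bundle.events if e.type == "cast")
        children = [e for e in bundle.events
                    if e.parentEventID == cast.eventID]
        assert len(children) == 103

    def test_reading_events_have_point_depths(self):
        bundle = generate(ScenarioSpec(category="ctd", seed=5, depths=10))
        readings = [e for e in bundle.events if "reading" in e.eventID]
        assert readings
        for ev in readings:
            assert ev.minimumDepthInMeters == ev.maximumDepthInMeters
            assert ev.minimumDepthInMeters is not None

    def test_derived_summary_is_single_cast_level_row(self):
        bundle = generate(ScenarioSpec(category="ctd", seed=9))
        cast = next(e for e in bundle.events if e.type == "cast")
        surface = [m for m in bundle.measurements
                   if m.measurementType == "Surface temperature"]
        assert len(surface) == 1
        assert surface[0].eventID == cast.eventID
        assert surface[0].occurrenceID == ""


class TestTelemetry:
    def test_positions_split_evenly_across_sections(self):
        bundle = generate(ScenarioSpec(category="telemetry", seed=2,
                                       sections=5, positions=50))
        for s in range(1, 6):
            positions = [e for e in bundle.events
                         if e.parentEventID == f"track1:section{s}"]
            assert len(positions) == 10

    def test_position_events_have_no_occurrence_measurements(self):
        bundle = generate(ScenarioSpec(category="telemetry", seed=2))
        position_ids = {e.eventID for e in bundle.events
                        if "position" in e.eventID}
        for m in bundle.measurements:
            if m.eventID in position_ids:
                assert m.occurrenceID == ""

    def test_biometrics_link_event_and_occurrence(self):
        bundle = generate(ScenarioSpec(category="telemetry", seed=2))
        biometric = [m for m in bundle.measurements
                     if m.measurementType in ("Body length", "Body mass")]
        assert biometric
        capture = next(e for e in bundle.events
                       if "capture" in e.eventID)
        for m in biometric:
            assert m.eventID == capture.eventID and m.occurrenceID

    def test_minimal_track(self):
        bundle = generate(ScenarioSpec(category="telemetry", seed=1,
                                       sections=1, positions=1))
        assert not validation.has_errors(
            validation.validate_bundle(bundle))


class TestVpr:
    def _sections(self, bundle):
        return [e for e in bundle.events
                if e.parentEventID == "tow1" and "section" in e.eventID]

    def test_forty_seconds_at_four_gives_ten_sections(self):
        bundle = generate(ScenarioSpec(category="vpr", seed=1,
                                       duration_s=40.0, interval_s=4.0))
        sections = self._sections(bundle)
        assert len(sections) == 10
        assert all("partial" not in e.extras.get("eventRemarks", "")
                   for e in sections)

    def test_short_tow_yields_one_flagged_partial_section(self):
        bundle = generate(ScenarioSpec(category="vpr", seed=1,
                                       duration_s=3.0, interval_s=4.0))
        sections = self._sections(bundle)
        assert len(sections) == 1
        assert "partial" in sections[0].extras.get("eventRemarks", "")

    def test_frame_rate_recorded_on_the_tow(self):
        bundle = generate(ScenarioSpec(category="vpr", seed=1))
        row = next(m for m in bundle.measurements
                   if m.measurementType == "Imaging frame rate")
        assert row.eventID == "tow1"
        assert row.measurementValue == "30"
        assert row.occurrenceID == ""


class TestRegistry:
    def test_thirteen_archetypes(self):
        entries = registry()
        assert len(entries) == 13
        titles = [t for t, _ in entries]
        assert len(set(titles)) == 13

    def test_biometrics_only_archetype(self):
        spec = dict(registry())["Sizing Ocean Giants"]
        assert spec.category == "sample_based"
        assert spec.biotic == ("biometrics",)
        bundle = generate(spec)
        types = {m.measurementType for m in bundle.measurements
                 if m.occurrenceID}
        assert types == {"Body length"}
        assert spec.abiotic is False

    def test_every_archetype_validates_and_round_trips(self, tmp_path):
        for i, (title, spec) in enumerate(registry()):
            bundle = generate(spec)
            issues = validation.validate_bundle(bundle)
            assert not validation.has_errors(issues), title
            path = archive.write_archive(bundle, tmp_path / f"{i}.zip")
            assert archive.read_archive(path).sorted_copy() == \
                bundle.sorted_copy(), title


class TestSpecs:
    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidSpecError):
            generate(ScenarioSpec(category="sonar"))
        with pytest.raises(InvalidSpecError):
            generate(ScenarioSpec(category="vpr", duration_s=0))
        with pytest.raises(InvalidSpecError):
            generate(ScenarioSpec(category="sample_based", stations=-1))
        with pytest.raises(InvalidSpecError):
            generate(ScenarioSpec(category="sample_based",
                                  biotic=("sonar",)))

    def test_spec_loadable_from_yaml_and_json(self, tmp_path):
        yml = tmp_path / "spec.yaml"
        yml.write_text("category: ctd\nseed: 4\ndepths: 7\n")
        spec = fixtures.spec_from_file(yml)
        assert (spec.category, spec.seed, spec.depths) == ("ctd", 4, 7)
        js = tmp_path / "spec.json"
        js.write_text('{"category": "vpr", "seed": 2, '
                      '"biotic": ["abundance"]}')
        spec = fixtures.spec_from_file(js)
        assert spec.biotic == ("abundance",)
        assert generate(spec)
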