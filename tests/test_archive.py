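"""Descriptor parsing/serialization and archive round trips."""

import io
import zipfile

import pytest
from hypothesis import given, strategies as st

from obisenv import archive as aio
from obisenv import fixtures, terms
from obisenv.errors import (DuplicateCoreError, LayoutMismatchError,
                            MalformedXMLError, MissingDescriptorError)
from obisenv.model import DatasetBundle, EventRecord

OPTION6_META = """<?xml version="1.0"?>
<archive xmlns="http://rs.tdwg.org/dwc/text/">
  <core rowType="http://rs.tdwg.org/dwc/terms/Event" encoding="UTF-8"
        fieldsTerminatedBy="\\t" ignoreHeaderLines="1">
    <files><location>event.txt</location></files>
    <id index="0"/>
    <field index="0" term="http://rs.tdwg.org/dwc/terms/eventID"/>
    <field index="1" term="http://rs.tdwg.org/dwc/terms/parentEventID"/>
  </core>
  <extension rowType="http://rs.tdwg.org/dwc/terms/Occurrence">
    <files><location>occurrence.txt</location></files>
    <coreid index="0"/>
    <field index="1" term="http://rs.tdwg.org/dwc/terms/occurrenceID"/>
    <field index="2" term="http://rs.tdwg.org/dwc/terms/scientificName"/>
  </extension>
  <extension rowType="http://rs.gbif.org/extension/obis/extended_measurement_or_fact.xml">
    <files><location>emof.txt</location></files>
    <coreid index="0"/>
    <field index="1" term="http://rs.tdwg.org/dwc/terms/occurrenceID"/>
    <field index="2" term="http://rs.tdwg.org/dwc/terms/measurementType"/>
    <field index="3" term="http://rs.tdwg.org/dwc/terms/measurementValue"/>
  </extension>
</archive>
"""


class TestParseDescriptor:
    def test_event_core_with_two_extensions(self):
        d = aio.parse_descriptor(OPTION6_META)
        assert d.core_row_type == "event"
        assert len(d.extensions) == 2
        assert {e.row_type for e in d.extensions} == {"occurrence", "emof"}
        assert d.delimiter == "\t"

    def test_two_cores_rejected(self):
        doubled = OPTION6_META.replace(
            "</core>", "</core><core rowType="
            "\"http://rs.tdwg.org/dwc/terms/Event\">"
            "<files><location>x.txt</location></files><id index=\"0\"/>"
            "</core>", 1)
        with pytest.raises(DuplicateCoreError):
            aio.parse_descriptor(doubled)

    def test_occurrence_core_descriptor(self):
        meta = """<archive xmlns="http://rs.tdwg.org/dwc/text/">
          <core rowType="http://rs.tdwg.org/dwc/terms/Occurrence">
            <files><location>occurrence.txt</location></files>
            <id index="0"/>
            <field index="0"
                   term="http://rs.tdwg.org/dwc/terms/occurrenceID"/>
          </core>
          <extension rowType="http://rs.gbif.org/extension/obis/extended_measurement_or_fact.xml">
            <files><location>emof.txt</location></files>
            <coreid index="0"/>
            <field index="1"
                   term="http://rs.tdwg.org/dwc/terms/measurementType"/>
          </extension>
        </archive>"""
        d = aio.parse_descriptor(meta)
        assert d.core_row_type == "occurrence"
        assert d.extensions[0].row_type == "emof"

    def test_malformed_xml(self):
        with pytest.raises(MalformedXMLError):
            aio.parse_descriptor("<archive><core>")

    @given(st.data())
    def test_serialize_parse_fidelity(self, data):
        """parse(serialize(d)) == d over random descriptors drawn from the
        registered term set."""
        event_terms = ["eventID", "parentEventID", "eventDate",
                       "decimalLatitude", "footprintWKT"]
        ext_terms = ["occurrenceID", "scientificName", "lifeStage",
                     "organismQuantity"]
        core_pick = ["eventID"] + data.draw(
            st.lists(st.sampled_from(event_terms[1:]), unique=True,
                     max_size=4))
        ext_pick = ["occurrenceID"] + data.draw(
            st.lists(st.sampled_from(ext_terms[1:]), unique=True,
                     max_size=3))
        d = aio.ArchiveDescriptor(
            core_row_type="event", core_file="event.txt",
            core_id_column=0,
            core_fields=tuple((t, i) for i, t in enumerate(core_pick)),
            extensions=(aio.ExtensionDescriptor(
                "occurrence", "occurrence.txt", 0,
                tuple((t, i + 1) for i, t in enumerate(ext_pick))),),
            delimiter=data.draw(st.sampled_from(["\t", ","])))
        assert aio.parse_descriptor(aio.serialize_descriptor(d)) == d


class TestReadWrite:
    def test_round_trip_identity(self, category_bundle, tmp_path):
        path = aio.write_archive(category_bundle, tmp_path / "a.zip")
        again = aio.read_archive(path)
        assert again.sorted_copy() == category_bundle.sorted_copy()

    def test_emof_occurrence_ids_survive(self, tmp_path):
        bundle = fixtures.generate(fixtures.ScenarioSpec(category="ctd",
                                                         seed=7))
        path = aio.write_archive(bundle, tmp_path / "ctd.zip", layout=6)
        again = aio.read_archive(path)
        assert again.emof_has_occurrence_id
        assert any(m.occurrenceID for m in again.measurements)

    def test_zip_without_descriptor(self, tmp_path):
        bad = tmp_path / "bad.zip"
        with zipfile.ZipFile(bad, "w") as zf:
            zf.writestr("event.txt", "eventID\n")
        with pytest.raises(MissingDescriptorError):
            aio.read_archive(bad)

    def test_empty_bundle_gives_header_only_files(self, tmp_path):
        path = aio.write_archive(DatasetBundle(), tmp_path / "empty.zip",
                                 layout=6)
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            assert {"meta.xml", "eml.xml", "event.txt",
                    "occurrence.txt",
                    "extendedmeasurementorfact.txt"} <= names
            for member in names - {"meta.xml", "eml.xml"}:
                assert len(zf.read(member).splitlines()) == 1
        again = aio.read_archive(path)
        assert not again.events and not again.measurements

    def test_layout_mismatch_directs_to_converter(self, tmp_path):
        bundle = DatasetBundle(events=[EventRecord(eventID="e1")])
        with pytest.raises(LayoutMismatchError, match="convert"):
            aio.write_archive(bundle, tmp_path / "x.zip", layout=1)

    def test_unpacked_directory_is_readable(self, tmp_path, fig1_bundle):
        path = aio.write_archive(fig1_bundle, tmp_path / "a.zip")
        outdir = tmp_path / "unpacked"
        with zipfile.ZipFile(path) as zf:
            zf.extractall(outdir)
        again = aio.read_archive(outdir)
        assert again.sorted_copy() == fig1_bundle.sorted_copy()

    def test_written_tables_match_descriptor_byte_level(self,
                                                        category_bundle,
                                                        tmp_path):
        """Independent re-parse: every data row has exactly the column
        count the descriptor maps."""
        path = aio.write_archive(category_bundle, tmp_path / "a.zip")
        with zipfile.ZipFile(path) as zf:
            d = aio.parse_descriptor(zf.read("meta.xml"))
            tables = [(d.core_file, d.core_fields)] + [
                (e.filename, e.fields) for e in d.extensions]
            for fname, mapped in tables:
                width = max(idx for _, idx in mapped) + 1
                text = zf.read(fname).decode("utf-8")
                for line in text.splitlines():
                    assert len(line.split("\t")) == width
                for term, _ in mapped:
                    terms.term_info(term)  # registry completeness
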