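"""Deterministic synthetic datasets for the four pilot-study categories.

Real combined datasets fall into four structural families: classic
sample-based surveys (grabs, trawls, corers, nets), CTD casts and CTD-like
profiles, animal telemetry/tagging tracks, and Video Plankton Recorder
tows.  Each generator here emulates one family's event hierarchy and
linkage structure — cruise/station/sample levels, reading-depth children
under a cast, capture/section/position events of a track, fixed-interval
sections of a tow — and fills measurement values from seeded pseudo-random
draws over plausible ranges with realistic units.  The structures are
faithful; the values are placeholders, not oceanographic physics.

The same :class:`ScenarioSpec` always yields an identical bundle, and
(through the fixed-timestamp archive writer) byte-identical zips, which is
what makes these generators usable as the test bed for every other module.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import InvalidSpecError
from .hierarchy import hierarchical_id
from .model import (DatasetBundle, EmlStub, EMoFRecord, EventRecord,
                    OccurrenceRecord)

__all__ = ["ScenarioSpec", "generate", "gen_sample_based", "gen_ctd",
           "gen_telemetry", "gen_vpr", "registry", "spec_from_file",
           "CATEGORIES"]

CATEGORIES = ("sample_based", "ctd", "telemetry", "vpr", "fig1")

_BENTHOS = ("Abra alba", "Echinocardium cordatum", "Lanice conchilega",
            "Nephtys hombergii")
_MEIOFAUNA = ("Richtersia inaequalis", "Sabatieria punctata")
_PLANKTON = ("Calanus finmarchicus", "Oithona similis",
             "Temora longicornis")


@dataclass(frozen=True)
class ScenarioSpec:
    """Size, noise and content knobs for one synthetic dataset.

    Defaults are small enough that a full registry sweep stays fast while
    still exercising every structural feature (multi-station hierarchies,
    partial VPR intervals, multi-section tracks).
    """

    category: str = "sample_based"
    seed: int = 1
    title: str = ""
    # sample-based
    stations: int = 2
    subsamples: int = 2
    taxa: int = 3
    # ctd
    depths: int = 20
    niskins: int = 3
    # telemetry
    sections: int = 4
    positions: int = 20          # total position events across all sections
    # vpr
    duration_s: float = 40.0
    interval_s: float = 4.0
    frame_rate: float = 30.0
    include_ctd: bool = True
    # content
    biotic: tuple[str, ...] = ("abundance", "biomass")
    abiotic: bool = True
    noise: float = 0.1           # relative spread of measurement values

    def validate(self) -> None:
        if self.category not in CATEGORIES:
            raise InvalidSpecError(f"unknown category {self.category!r}")
        if min(self.stations, self.subsamples, self.taxa, self.depths,
               self.niskins, self.sections, self.positions) < 0:
            raise InvalidSpecError("size parameters must be >= 0")
        if self.category == "vpr" and (self.duration_s <= 0
                                       or self.interval_s <= 0):
            raise InvalidSpecError("duration and interval must be > 0")
        if self.category == "telemetry" and self.sections == 0:
            raise InvalidSpecError("telemetry needs at least one section")
        unknown = set(self.biotic) - {"abundance", "biomass", "biometrics",
                                      "presence"}
        if unknown:
            raise InvalidSpecError(f"unknown biotic kinds {sorted(unknown)}")


def spec_from_file(path: str | Path) -> ScenarioSpec:
    """Load a ScenarioSpec from a YAML or JSON config file."""
    text = Path(path).read_text(encoding="utf-8")
    data = (json.loads(text) if str(path).endswith(".json")
            else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise InvalidSpecError(f"spec file {path} must hold a mapping")
    if "biotic" in data:
        data["biotic"] = tuple(data["biotic"])
    try:
        spec = ScenarioSpec(**data)
    except TypeError as exc:
        raise InvalidSpecError(str(exc)) from None
    spec.validate()
    return spec


def generate(spec: ScenarioSpec) -> DatasetBundle:
    """Dispatch to the category's generator."""
    spec.validate()
    producer = {"sample_based": gen_sample_based, "fig1": gen_sample_based,
                "ctd": gen_ctd, "telemetry": gen_telemetry,
                "vpr": gen_vpr}[spec.category]
    return producer(spec)


# --------------------------------------------------------------------------
# shared helpers
# --------------------------------------------------------------------------

def _round(value: float, digits: int = 3) -> float:
    return round(value, digits)


def _value(rng: random.Random, mean: float, spread: float,
           digits: int = 2) -> str:
    v = mean * (1.0 + spread * (2.0 * rng.random() - 1.0))
    return f"{v:.{digits}f}"


class _Builder:
    """Accumulates records and hands out deterministic identifiers."""

    def __init__(self, spec: ScenarioSpec, title: str, abstract: str):
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.bundle = DatasetBundle(
            metadata=EmlStub(title=title or spec.title or "Synthetic "
                             f"{spec.category} dataset",
                             abstract=abstract,
                             creators=("Synthetic data generator",)),
            schema_option=6, emof_has_occurrence_id=True)
        self._occ_counter = 0
        self._meas_counter = 0

    def event(self, path: list[str], **fields) -> EventRecord:
        parent = hierarchical_id(path[:-1]) if len(path) > 1 else ""
        ev = EventRecord(eventID=hierarchical_id(path),
                         parentEventID=parent, **fields)
        self.bundle.events.append(ev)
        return ev

    def occurrence(self, event: EventRecord, name: str,
                   **fields) -> OccurrenceRecord:
        self._occ_counter += 1
        occ = OccurrenceRecord(
            occurrenceID=f"{event.eventID}#occ{self._occ_counter}",
            eventID=event.eventID, scientificName=name,
            basisOfRecord=fields.pop("basisOfRecord", "HumanObservation"),
            **fields)
        self.bundle.occurrences.append(occ)
        return occ

    def measure(self, event: EventRecord, mtype: str, value: str,
                unit: str = "", occurrence: OccurrenceRecord | None = None,
                **fields) -> EMoFRecord:
        self._meas_counter += 1
        m = EMoFRecord(
            eventID=event.eventID,
            occurrenceID=occurrence.occurrenceID if occurrence else "",
            measurementID=f"m{self._meas_counter}",
            measurementType=mtype, measurementValue=value,
            measurementUnit=unit, **fields)
        self.bundle.measurements.append(m)
        return m

    def biotic_rows(self, event: EventRecord, occ: OccurrenceRecord) -> None:
        """Quantifications/biometrics per the spec's biotic kinds."""
        rng, noise = self.rng, self.spec.noise
        if "abundance" in self.spec.biotic:
            self.measure(event, "Abundance",
                         _value(rng, 120.0, noise, 1),
                         "individuals per square metre", occ)
        if "biomass" in self.spec.biotic:
            self.measure(event, "Wet weight biomass",
                         _value(rng, 4.5, noise), "g/m2", occ)
        if "biometrics" in self.spec.biotic:
            self.measure(event, "Body length",
                         _value(rng, 35.0, noise, 1), "cm", occ)
        # "presence" adds no measurement rows: the occurrence itself is
        # the observation


# --------------------------------------------------------------------------
# sample-based surveys (incl. the multi-gear scenario)
# --------------------------------------------------------------------------

def gen_sample_based(spec: ScenarioSpec) -> DatasetBundle:
    """Cruise → station → gear deployments → (subsamples).

    Each station is visited with a Van Veen grab and a multi-corer (point
    geometries) and a beam trawl whose track is a WKT line.  Macrobenthos
    occurrences hang off the grab sample; meiofauna occurrences off
    subsample slices of the core; sediment measurements sit at sample or
    subsample level; the gear is recorded as a sampling-attribute fact.
    """
    if spec.category not in ("sample_based", "fig1"):
        raise InvalidSpecError(f"category {spec.category!r} is not "
                               "sample based")
    b = _Builder(spec, spec.title,
                 "Benthic survey with grab, beam trawl and multi-corer "
                 "sampling; abundances, biomass and sediment data.")
    rng = b.rng
    cruise = b.event(["cruise1"], type="cruise", eventDate="2016-05",
                     samplingProtocol="research cruise")
    for s in range(1, spec.stations + 1):
        lat = _round(51.0 + s * 0.2 + rng.uniform(-0.05, 0.05))
        lon = _round(2.5 + s * 0.3 + rng.uniform(-0.05, 0.05))
        day = f"2016-05-{min(s + 9, 28):02d}"
        station = b.event(["cruise1", f"station{s}"], type="station",
                          eventDate=day, decimalLatitude=lat,
                          decimalLongitude=lon)
        path = ["cruise1", f"station{s}"]

        grab = b.event(path + ["grab1"], type="sample", eventDate=day,
                       decimalLatitude=_round(lat + 0.001),
                       decimalLongitude=_round(lon + 0.001),
                       samplingProtocol="Van Veen grab",
                       sampleSizeValue=0.1, sampleSizeUnit="m2")
        b.measure(grab, "Sampling instrument name", "Van Veen grab")
        if spec.abiotic:
            b.measure(grab, "Sediment median grain size",
                      _value(rng, 210.0, spec.noise, 1), "um")
        for name in _BENTHOS[:max(1, spec.taxa)]:
            occ = b.occurrence(grab, name)
            b.biotic_rows(grab, occ)

        mcr = b.event(path + ["multicorer1"], type="sample", eventDate=day,
                      decimalLatitude=_round(lat - 0.001),
                      decimalLongitude=_round(lon - 0.001),
                      samplingProtocol="multi-corer")
        b.measure(mcr, "Sampling instrument name", "Multi-corer")
        for sub in range(1, spec.subsamples + 1):
            top, bottom = (sub - 1) * 0.02, sub * 0.02
            slice_ev = b.event(
                path + ["multicorer1", f"slice{sub}"], type="subsample",
                minimumDepthInMeters=top, maximumDepthInMeters=bottom,
                samplingProtocol="core slice")
            if spec.abiotic:
                b.measure(slice_ev, "Organic carbon content",
                          _value(rng, 1.2, spec.noise), "percent")
            for name in _MEIOFAUNA[:max(1, min(spec.taxa, 2))]:
                occ = b.occurrence(slice_ev, name)
                b.biotic_rows(slice_ev, occ)

        trawl = b.event(
            path + ["trawl1"], type="sample", eventDate=day,
            footprintWKT=(f"LINESTRING ({_round(lon)} {_round(lat)}, "
                          f"{_round(lon + 0.02)} {_round(lat + 0.01)})"),
            samplingProtocol="beam trawl")
        b.measure(trawl, "Sampling instrument name", "Beam trawl")
        for name in _BENTHOS[max(1, spec.taxa):][:1] or _BENTHOS[:1]:
            occ = b.occurrence(trawl, name)
            b.biotic_rows(trawl, occ)
    return b.bundle


# --------------------------------------------------------------------------
# CTD casts
# --------------------------------------------------------------------------

def gen_ctd(spec: ScenarioSpec) -> DatasetBundle:
    """A CTD cast with one child event per reading depth plus Niskin
    bottle children.

    Sensor readings taken at one time and depth form one child event of the
    cast, so each temperature/salinity pair is stored once instead of being
    duplicated per occurrence.  Water samples from the Niskin bottles are
    further children carrying microplankton occurrences, and a derived
    summary (surface temperature) sits at cast level as a single
    event-level row.
    """
    if spec.category != "ctd":
        raise InvalidSpecError(f"category {spec.category!r} is not ctd")
    b = _Builder(spec, spec.title,
                 "CTD profile with Niskin bottle samples and "
                 "microplankton counts.")
    rng = b.rng
    lat, lon = _round(54.0 + rng.uniform(-1, 1)), _round(3.0 + rng.uniform(-1, 1))
    cast = b.event(["cast1"], type="cast", eventDate="2016-06-03T10:30",
                   decimalLatitude=lat, decimalLongitude=lon,
                   samplingProtocol="CTD rosette cast")
    b.measure(cast, "Sampling instrument name", "CTD")
    surface_t = _value(rng, 14.0, spec.noise)
    b.measure(cast, "Surface temperature", surface_t, "degC",
              measurementRemarks="derived from the profile")

    max_depth = 5.0 * max(spec.depths, 1)
    for d in range(1, spec.depths + 1):
        depth = _round(d * max_depth / max(spec.depths, 1), 1)
        reading = b.event(["cast1", f"reading{d:04d}"], type="sample",
                          minimumDepthInMeters=depth,
                          maximumDepthInMeters=depth)
        b.measure(reading, "Temperature of the water body",
                  _value(rng, 14.0 - 8.0 * d / max(spec.depths, 1),
                         spec.noise), "degC")
        b.measure(reading, "Practical salinity",
                  _value(rng, 35.0, spec.noise * 0.1), "Dmnless")

    for n in range(1, spec.niskins + 1):
        depth = _round(n * max_depth / max(spec.niskins + 1, 1), 1)
        niskin = b.event(["cast1", f"niskin{n}"], type="sample",
                         minimumDepthInMeters=depth,
                         maximumDepthInMeters=depth,
                         samplingProtocol="Niskin bottle",
                         sampleSizeValue=10.0, sampleSizeUnit="l")
        if spec.abiotic:
            b.measure(niskin, "Chlorophyll-a concentration",
                      _value(rng, 2.0, spec.noise), "mg/m3")
        for name in _PLANKTON[:max(1, spec.taxa)]:
            occ = b.occurrence(niskin, name)
            b.measure(niskin, "Abundance",
                      _value(rng, 800.0, spec.noise, 0),
                      "individuals per cubic metre", occ)
    return b.bundle


# --------------------------------------------------------------------------
# telemetry / tagging tracks
# --------------------------------------------------------------------------

def gen_telemetry(spec: ScenarioSpec) -> DatasetBundle:
    """A tracked animal: capture → tracking sections → recovery.

    Biometrics measured at tagging link to the capture occurrence (both
    eventID and occurrenceID).  Each section — a grouping of readings from
    the same period and area, here a fixed-size block of positions — is
    linked to an occurrence record of the animal; the GPS position child
    events carry coordinates and abiotic readings but never an occurrence.
    """
    if spec.category != "telemetry":
        raise InvalidSpecError(f"category {spec.category!r} is not "
                               "telemetry")
    b = _Builder(spec, spec.title,
                 "Animal telemetry track: capture biometrics, tracking "
                 "sections with GPS positions, recovery.")
    rng = b.rng
    animal = "Larus fuscus"
    track = b.event(["track1"], type="cruise", eventDate="2016-04",
                    samplingProtocol="GPS tracking deployment")
    lat0, lon0 = 51.2, 2.9
    capture = b.event(["track1", "capture1"], type="station",
                      eventDate="2016-04-02",
                      decimalLatitude=lat0, decimalLongitude=lon0)
    cap_occ = b.occurrence(capture, animal)
    b.measure(capture, "Body length", _value(rng, 55.0, spec.noise, 1),
              "cm", cap_occ)
    b.measure(capture, "Body mass", _value(rng, 820.0, spec.noise, 0),
              "g", cap_occ)

    per_section, extra = divmod(spec.positions, spec.sections)
    pos_counter = 0
    for s in range(1, spec.sections + 1):
        section = b.event(["track1", f"section{s}"], type="station",
                          eventDate=f"2016-04-{min(2 + s, 28):02d}")
        b.occurrence(section, animal, basisOfRecord="MachineObservation")
        count = per_section + (1 if s <= extra else 0)
        for p in range(1, count + 1):
            pos_counter += 1
            lat = _round(lat0 + 0.01 * pos_counter + rng.uniform(-0.002, 0.002), 4)
            lon = _round(lon0 + 0.008 * pos_counter + rng.uniform(-0.002, 0.002), 4)
            position = b.event(
                ["track1", f"section{s}", f"position{p:03d}"],
                type="sample",
                eventDate=f"2016-04-{min(2 + s, 28):02d}T"
                          f"{(6 + p) % 24:02d}:00",
                decimalLatitude=lat, decimalLongitude=lon)
            if spec.abiotic:
                b.measure(position, "Air temperature",
                          _value(rng, 11.0, spec.noise), "degC")

    b.event(["track1", "recovery1"], type="station",
            eventDate="2016-05-20", decimalLatitude=lat0,
            decimalLongitude=lon0,
            samplingProtocol="tag recovery")
    return b.bundle


# --------------------------------------------------------------------------
# Video Plankton Recorder tows
# --------------------------------------------------------------------------

def gen_vpr(spec: ScenarioSpec) -> DatasetBundle:
    """A VPR tow split into fixed software-grouping intervals.

    With the default 4 s grouping and 30 frames/s, a 40 s tow yields 10
    full section events; a trailing partial interval becomes one extra
    section flagged in eventRemarks rather than being dropped.  Plankton
    abundances per section link occurrences and eMoF rows; the frame rate
    is a sampling-attribute fact on the tow; optionally a raw CTD chain
    hangs off the tow as well.
    """
    if spec.category != "vpr":
        raise InvalidSpecError(f"category {spec.category!r} is not vpr")
    b = _Builder(spec, spec.title,
                 "Video Plankton Recorder tow with software-grouped "
                 "section events and plankton abundances.")
    rng = b.rng
    lat0, lon0 = 41.5, -67.5
    tow = b.event(["tow1"], type="cruise", eventDate="2016-07-11",
                  decimalLatitude=lat0, decimalLongitude=lon0,
                  samplingProtocol="Video Plankton Recorder tow")
    b.measure(tow, "Imaging frame rate", f"{spec.frame_rate:g}",
              "frames per second")
    b.measure(tow, "Sampling instrument name", "Video Plankton Recorder")

    full, remainder = divmod(spec.duration_s, spec.interval_s)
    n_full = int(full)
    for s in range(1, n_full + 1):
        section = b.event(
            ["tow1", f"section{s:03d}"], type="sample",
            decimalLatitude=_round(lat0 + 0.001 * s, 4),
            decimalLongitude=_round(lon0 + 0.001 * s, 4),
            samplingProtocol=f"{spec.interval_s:g} s software grouping")
        for name in _PLANKTON[:max(1, spec.taxa)]:
            occ = b.occurrence(section, name,
                               basisOfRecord="MachineObservation")
            b.measure(section, "Abundance",
                      _value(rng, 60.0, spec.noise, 0),
                      "individuals per cubic metre", occ)
    if remainder > 1e-9:
        section = b.event(
            ["tow1", f"section{n_full + 1:03d}"], type="sample",
            decimalLatitude=_round(lat0 + 0.001 * (n_full + 1), 4),
            decimalLongitude=_round(lon0 + 0.001 * (n_full + 1), 4),
            extras={"eventRemarks": f"partial interval: {remainder:g} s "
                                    f"of {spec.interval_s:g} s"})
        occ = b.occurrence(section, _PLANKTON[0],
                           basisOfRecord="MachineObservation")
        b.measure(section, "Abundance", _value(rng, 60.0, spec.noise, 0),
                  "individuals per cubic metre", occ)

    if spec.include_ctd and spec.depths > 0:
        ctd = b.event(["tow1", "ctd1"], type="sample",
                      samplingProtocol="CTD on tow frame")
        for d in range(1, min(spec.depths, 5) + 1):
            reading = b.event(["tow1", "ctd1", f"reading{d:04d}"],
                              type="subsample",
                              minimumDepthInMeters=float(d * 2),
                              maximumDepthInMeters=float(d * 2))
            b.measure(reading, "Temperature of the water body",
                      _value(rng, 16.0, spec.noise), "degC")
        b.measure(ctd, "Sampling instrument name", "CTD")
    return b.bundle


# --------------------------------------------------------------------------
# pilot-dataset archetypes
# --------------------------------------------------------------------------

def registry() -> list[tuple[str, ScenarioSpec]]:
    """The 13 pilot-dataset archetypes: (title, spec) pairs.

    One archetype per pilot dataset, mapped to the structural category and
    content kinds of the original (tag-detection datasets reuse the
    telemetry generator, with sections as receiver-window groupings).
    """
    entries = [
        ("Fish lengths and distribution during the BROKE-West survey",
         ScenarioSpec(category="ctd", seed=101, taxa=2,
                      biotic=("biometrics",))),
        ("IMOS - AATAMS Facility - Satellite Relay Tagging Program - "
         "Near real-time CTD profile data",
         ScenarioSpec(category="telemetry", seed=102, sections=3,
                      positions=12, biotic=("biometrics",))),
        ("BCO-DMO: Georges Bank VPR data",
         ScenarioSpec(category="vpr", seed=103, duration_s=40.0,
                      interval_s=4.0, biotic=("abundance",))),
        ("BCO-DMO: Zooplankton abundance & biomass from MOCNESS "
         "Gulf of Maine",
         ScenarioSpec(category="sample_based", seed=104, stations=2,
                      biotic=("abundance", "biomass"))),
        ("Ascent phase of the dives of one elephant seal",
         ScenarioSpec(category="telemetry", seed=105, sections=2,
                      positions=10, biotic=("presence",))),
        ("North Sea Benthos Survey",
         ScenarioSpec(category="sample_based", seed=106, stations=3,
                      biotic=("abundance", "biomass"))),
        ("Hyperbenthic communities of the North Sea",
         ScenarioSpec(category="sample_based", seed=107, stations=2,
                      subsamples=3, biotic=("abundance", "biomass"))),
        ("Bird tracking - GPS tracking of Lesser Black-backed Gulls and "
         "Herring Gulls breeding at the southern North Sea coast",
         ScenarioSpec(category="telemetry", seed=108, sections=4,
                      positions=20, biotic=("presence",))),
        ("Benthic communities in Amvrakikos Wetlands: Mazoma, Tsopeli, "
         "Tsoukalio, Rodia and Logarou lagoons "
         "(September 2010 - July 2011)",
         ScenarioSpec(category="sample_based", seed=109, stations=3,
                      biotic=("abundance",))),
        ("Siganids Southcoast Kenya",
         ScenarioSpec(category="sample_based", seed=110, stations=1,
                      biotic=("biometrics",), abiotic=False)),
        ("USGS South Florida Fish and Invertebrate Assessment Network "
         "Harvest",
         ScenarioSpec(category="sample_based", seed=111, stations=2,
                      biotic=("biomass",))),
        ("Phytoplankton and abiotical data North Adriatic Gulf of "
         "Trieste LTER time-series",
         ScenarioSpec(category="ctd", seed=112, depths=10, niskins=4,
                      biotic=("abundance",))),
        ("Sizing Ocean Giants",
         ScenarioSpec(category="sample_based", seed=113, stations=1,
                      taxa=1, biotic=("biometrics",), abiotic=False)),
    ]
    return [(title, _with_title(spec, title)) for title, spec in entries]


def _with_title(spec: ScenarioSpec, title: str) -> ScenarioSpec:
    data = asdict(spec)
    data["title"] = title
    data["biotic"] = tuple(data["biotic"])
    return ScenarioSpec(**data)
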