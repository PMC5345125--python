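"""Registry of the Darwin Core and ExtendedMeasurementOrFact terms in use.

The ExtendedMeasurementOrFact (eMoF) extension is the MeasurementOrFact
extension plus four terms: ``occurrenceID`` (a cross-link from a measurement
to the Occurrence extension) and ``measurementTypeID`` / ``measurementValueID``
/ ``measurementUnitID`` (persistent identifiers into controlled
vocabularies).  Those four carry ``source="obis-emof"``; everything else in
the registry is either a ratified Darwin Core term (``dwc-core``) or a term
from a GBIF-registered extension (``gbif-extension``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UnknownTermError

DWC = "http://rs.tdwg.org/dwc/terms/"
DCTERMS = "http://purl.org/dc/terms/"
IOBIS = "http://rs.iobis.org/obis/terms/"

#: rowType URI of the eMoF extension as registered with GBIF.
EMOF_ROWTYPE = "http://rs.gbif.org/extension/obis/extended_measurement_or_fact.xml"
#: rowType URI of the classic MeasurementOrFact extension (no occurrenceID).
MOF_ROWTYPE = "http://rs.gbif.org/terms/1.0/MeasurementOrFact"
EVENT_ROWTYPE = DWC + "Event"
OCCURRENCE_ROWTYPE = DWC + "Occurrence"


@dataclass(frozen=True)
class TermDescriptor:
    """One vocabulary term: its label, persistent URI, origin and meaning."""

    name: str
    uri: str
    source: str  # one of {"dwc-core", "obis-emof", "gbif-extension"}
    definition: str = ""


def _dwc(name: str, definition: str = "") -> TermDescriptor:
    return TermDescriptor(name, DWC + name, "dwc-core", definition)


_TERMS: list[TermDescriptor] = [
    # --- event fields -----------------------------------------------------
    _dwc("eventID", "An identifier for the sampling event."),
    _dwc("parentEventID", "The eventID of the broader event this event "
         "belongs to; creates the sampling-event hierarchy."),
    TermDescriptor("type", DCTERMS + "type", "dwc-core",
                   "The level of an event in the hierarchy; recommended "
                   "values include cruise, station, sample and subsample."),
    _dwc("eventDate", "Date or interval of the event, ISO 8601."),
    _dwc("eventTime"),
    _dwc("year"), _dwc("month"), _dwc("day"),
    _dwc("decimalLatitude", "Latitude in decimal degrees, WGS84."),
    _dwc("decimalLongitude", "Longitude in decimal degrees, WGS84."),
    _dwc("geodeticDatum"),
    _dwc("coordinateUncertaintyInMeters"),
    _dwc("footprintWKT", "Well-Known-Text geometry of the sampling "
         "footprint, e.g. a trawl track as a LINESTRING."),
    _dwc("minimumDepthInMeters"),
    _dwc("maximumDepthInMeters"),
    _dwc("samplingProtocol"),
    _dwc("samplingEffort"),
    _dwc("sampleSizeValue"),
    _dwc("sampleSizeUnit"),
    _dwc("habitat"),
    _dwc("locality"),
    _dwc("locationID"),
    _dwc("waterBody"),
    _dwc("country"),
    _dwc("countryCode"),
    _dwc("fieldNumber"),
    _dwc("eventRemarks"),
    _dwc("institutionCode"),
    _dwc("datasetName"),
    # --- occurrence fields ------------------------------------------------
    _dwc("scientificName"),
    _dwc("scientificNameID", "URI of the taxon name, e.g. a WoRMS LSID."),
    _dwc("basisOfRecord"),
    _dwc("organismQuantity"),
    _dwc("organismQuantityType"),
    _dwc("individualCount"),
    _dwc("occurrenceStatus"),
    _dwc("occurrenceRemarks"),
    _dwc("lifeStage"),
    _dwc("sex"),
    _dwc("kingdom"), _dwc("phylum"), _dwc("class"), _dwc("order"),
    _dwc("family"), _dwc("genus"), _dwc("taxonRank"),
    _dwc("identifiedBy"),
    _dwc("recordedBy"),
    _dwc("associatedMedia"),
    _dwc("dynamicProperties"),
    # --- measurement-or-fact fields ---------------------------------------
    _dwc("measurementID", "An identifier for the measurement or fact."),
    _dwc("measurementType", "The nature of the measurement, fact, "
         "characteristic or assertion; best practice is a controlled "
         "vocabulary."),
    _dwc("measurementValue", "The value of the measurement, fact, "
         "characteristic, or assertion."),
    _dwc("measurementAccuracy"),
    _dwc("measurementUnit", "The unit expression for the measurement; "
         "best practice is SI."),
    _dwc("measurementDeterminedDate"),
    _dwc("measurementDeterminedBy"),
    _dwc("measurementMethod"),
    _dwc("measurementRemarks", "Comments or notes accompanying the "
         "MeasurementOrFact."),
    # --- the four terms the eMoF extension adds ---------------------------
    TermDescriptor("occurrenceID", DWC + "occurrenceID", "obis-emof",
                   "The identifier of the occurrence the measurement or "
                   "fact refers to; left empty for event-level rows."),
    TermDescriptor("measurementTypeID", IOBIS + "measurementTypeID",
                   "obis-emof",
                   "URI identifying the measurementType in a controlled "
                   "vocabulary."),
    TermDescriptor("measurementValueID", IOBIS + "measurementValueID",
                   "obis-emof",
                   "URI identifying a fact value (instrument name, life "
                   "stage, ...); meaningless, and left empty, for numeric "
                   "values."),
    TermDescriptor("measurementUnitID", IOBIS + "measurementUnitID",
                   "obis-emof",
                   "URI identifying the measurementUnit in a controlled "
                   "vocabulary."),
]

_REGISTRY: dict[str, TermDescriptor] = {t.name: t for t in _TERMS}

#: The four terms the eMoF extension adds over plain MeasurementOrFact.
EMOF_NEW_TERMS = ("occurrenceID", "measurementTypeID",
                  "measurementValueID", "measurementUnitID")


def term_info(name: str) -> TermDescriptor:
    """Look up a term by label; raises :class:`UnknownTermError` if absent."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise UnknownTermError(name) from None


def known_terms() -> frozenset[str]:
    return frozenset(_REGISTRY)
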