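"""In-memory model of one combined biological/environmental dataset.

A dataset is a :class:`DatasetBundle`: sampling events, species occurrences
and ExtendedMeasurementOrFact (eMoF) rows, plus a minimal metadata stub.
Records use plain dataclasses; absent values are ``None`` for numeric fields
and ``""`` for text fields, which serialize to the empty string in tabular
form and convert back losslessly.

Biotic measurements carry both an ``eventID`` and an ``occurrenceID``;
abiotic measurements and sampling-attribute facts carry only an ``eventID``.
That linkage convention is the heart of the format and is what the
:mod:`obisenv.validation` rules enforce.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields as dc_fields, replace

from .errors import MalformedValueError, UnknownTermError
from .terms import known_terms, term_info

__all__ = [
    "EventRecord", "OccurrenceRecord", "EMoFRecord", "EmlStub",
    "DatasetBundle", "make_record", "get_field", "set_field",
    "is_numeric_literal", "is_iso8601", "format_number",
    "EVENT_FIELDS", "OCCURRENCE_FIELDS", "EMOF_FIELDS",
]

_NUMBER_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")

# ISO 8601: a (possibly reduced-precision) date, optional time with optional
# zone designator, optionally an interval "start/end".
_ISO_PART_RE = re.compile(
    r"^\d{4}(-(0[1-9]|1[0-2])(-(0[1-9]|[12]\d|3[01])"
    r"(T([01]\d|2[0-3]):[0-5]\d(:[0-5]\d(\.\d+)?)?"
    r"(Z|[+-]([01]\d|2[0-3]):?[0-5]\d)?)?)?)?$"
)


def is_numeric_literal(text: str) -> bool:
    """True when *text* is a plain number (optional sign, decimal point,
    exponent).  Facts such as ``"WP-2"`` or ``"alive"`` are not numbers."""
    return bool(_NUMBER_RE.match(text.strip()))


def is_iso8601(text: str) -> bool:
    """Syntactic ISO 8601 check for dates, date-times and intervals.

    Values are stored verbatim; no timezone normalization is attempted.
    """
    parts = text.split("/")
    if len(parts) > 2:
        return False
    return all(_ISO_PART_RE.match(p) for p in parts)


def format_number(value: float) -> str:
    """Shortest decimal text that reads back to the same float."""
    text = repr(float(value))
    return text[:-2] if text.endswith(".0") else text


@dataclass
class EventRecord:
    """One sampling event (a cruise, station visit, gear deployment, ...)."""

    eventID: str
    parentEventID: str = ""
    type: str = ""  # hierarchy level label: cruise | station | sample | ...
    eventDate: str = ""
    decimalLatitude: float | None = None
    decimalLongitude: float | None = None
    footprintWKT: str = ""
    minimumDepthInMeters: float | None = None
    maximumDepthInMeters: float | None = None
    samplingProtocol: str = ""
    sampleSizeValue: float | None = None
    sampleSizeUnit: str = ""
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class OccurrenceRecord:
    """One taxon observation, linked to exactly one event.

    ``organismQuantity``/``organismQuantityType`` are retained for reading
    third-party archives even though quantifications belong in the eMoF; the
    validator flags double encoding (rule R8) rather than this class.
    """

    occurrenceID: str
    eventID: str = ""
    scientificName: str = ""
    scientificNameID: str = ""
    basisOfRecord: str = ""
    organismQuantity: float | None = None
    organismQuantityType: str = ""
    extras: dict[str, str] = field(default_factory=dict)


@dataclass
class EMoFRecord:
    """One measurement or fact from the eMoF extension (14 columns).

    An empty ``occurrenceID`` means the row is event-level (an abiotic
    measurement or a sampling attribute); a non-empty one marks a biotic
    row attached to that occurrence.
    """

    eventID: str = ""
    measurementID: str = ""
    occurrenceID: str = ""
    measurementType: str = ""
    measurementTypeID: str = ""
    measurementValue: str = ""
    measurementValueID: str = ""
    measurementAccuracy: str = ""
    measurementUnit: str = ""
    measurementUnitID: str = ""
    measurementDeterminedDate: str = ""
    measurementDeterminedBy: str = ""
    measurementMethod: str = ""
    measurementRemarks: str = ""


@dataclass
class EmlStub:
    """Minimal dataset metadata (full EML authoring is out of scope)."""

    title: str = ""
    abstract: str = ""
    creators: tuple[str, ...] = ()


@dataclass
class DatasetBundle:
    """One logical dataset: events + occurrences + measurements + metadata.

    ``schema_option`` declares the layout the content follows (one of
    ``1, 2, 4, 5, 6`` or ``"unknown"``).  ``emof_has_occurrence_id`` records
    whether the measurement table carries an occurrenceID column at all —
    the feature that distinguishes the eMoF from the classic
    MeasurementOrFact extension.
    """

    events: list[EventRecord] = field(default_factory=list)
    occurrences: list[OccurrenceRecord] = field(default_factory=list)
    measurements: list[EMoFRecord] = field(default_factory=list)
    metadata: EmlStub = field(default_factory=EmlStub)
    schema_option: int | str = "unknown"
    emof_has_occurrence_id: bool = True

    def sorted_copy(self) -> "DatasetBundle":
        """Canonically ordered copy (sort by primary ID) for comparisons."""
        return replace(
            self,
            events=sorted((replace(e) for e in self.events),
                          key=lambda e: e.eventID),
            occurrences=sorted((replace(o) for o in self.occurrences),
                               key=lambda o: o.occurrenceID),
            measurements=sorted(
                (replace(m) for m in self.measurements),
                key=lambda m: (m.eventID, m.occurrenceID,
                               m.measurementType, m.measurementValue,
                               m.measurementID)),
        )


_KINDS = {"event": EventRecord, "occurrence": OccurrenceRecord,
          "emof": EMoFRecord}

EVENT_FIELDS = tuple(f.name for f in dc_fields(EventRecord)
                     if f.name != "extras")
OCCURRENCE_FIELDS = tuple(f.name for f in dc_fields(OccurrenceRecord)
                          if f.name != "extras")
EMOF_FIELDS = tuple(f.name for f in dc_fields(EMoFRecord))

_NUMERIC_FIELDS = {"decimalLatitude", "decimalLongitude",
                   "minimumDepthInMeters", "maximumDepthInMeters",
                   "sampleSizeValue", "organismQuantity"}
_DATE_FIELDS = {"eventDate", "measurementDeterminedDate"}


def _parse_number(term: str, value) -> float | None:
    if value is None or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise MalformedValueError(f"{term}: not a number: {value!r}") from None


def make_record(kind: str, fields: dict[str, object]):
    """Build a typed record from a ``term -> value`` mapping.

    Values may be strings (as read from a data table) or already-typed
    numbers.  Numeric and date fields are syntactically checked; coordinates
    and depths are range-checked.  Registered Darwin Core terms that are not
    canonical fields of the record go into ``extras``; unregistered keys
    raise :class:`UnknownTermError`.
    """
    try:
        cls = _KINDS[kind]
    except KeyError:
        raise ValueError(f"unknown record kind: {kind!r}") from None
    canonical = {"event": EVENT_FIELDS, "occurrence": OCCURRENCE_FIELDS,
                 "emof": EMOF_FIELDS}[kind]

    kwargs: dict[str, object] = {}
    extras: dict[str, str] = {}
    for term, value in fields.items():
        if term not in canonical:
            if kind == "emof" or term not in known_terms():
                raise UnknownTermError(term)
            term_info(term)  # registry completeness guard
            extras[term] = "" if value is None else str(value)
            continue
        if term in _NUMERIC_FIELDS:
            kwargs[term] = _parse_number(term, value)
        else:
            kwargs[term] = "" if value is None else str(value)

    record = cls(**kwargs) if kind == "emof" else cls(**kwargs, extras=extras)
    _check_record(kind, record)
    return record


def _check_record(kind: str, record) -> None:
    if kind == "event":
        if not record.eventID:
            raise MalformedValueError("eventID must be non-empty")
        _check_coords(record.decimalLatitude, record.decimalLongitude)
        lo, hi = record.minimumDepthInMeters, record.maximumDepthInMeters
        if lo is not None and hi is not None and lo > hi:
            raise MalformedValueError(
                f"minimumDepthInMeters {lo} exceeds maximumDepthInMeters {hi}")
    elif kind == "occurrence":
        if not record.occurrenceID:
            raise MalformedValueError("occurrenceID must be non-empty")
    elif kind == "emof":
        if not record.measurementType:
            raise MalformedValueError("measurementType must be non-empty")
    for name in _DATE_FIELDS:
        value = getattr(record, name, "")
        if value and not is_iso8601(value):
            raise MalformedValueError(f"{name}: not ISO 8601: {value!r}")


def _check_coords(lat: float | None, lon: float | None) -> None:
    if lat is not None and not -90.0 <= lat <= 90.0:
        raise MalformedValueError(f"decimalLatitude out of range: {lat}")
    if lon is not None and not -180.0 <= lon <= 180.0:
        raise MalformedValueError(f"decimalLongitude out of range: {lon}")


def get_field(record, term: str) -> str:
    """Read a field by term label, as text ('' when absent)."""
    if hasattr(record, term) and term != "extras":
        value = getattr(record, term)
        if value is None:
            return ""
        if isinstance(value, float):
            return format_number(value)
        return str(value)
    extras = getattr(record, "extras", None)
    if extras is not None and term in extras:
        return extras[term]
    return ""


def set_field(record, term: str, value: str) -> None:
    """Write a field by term label from its text form."""
    if hasattr(record, term) and term != "extras":
        if term in _NUMERIC_FIELDS:
            setattr(record, term, _parse_number(term, value))
        else:
            setattr(record, term, value)
    else:
        extras = getattr(record, "extras", None)
        if extras is None:
            raise UnknownTermError(term)
        term_info(term)
        extras[term] = value
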