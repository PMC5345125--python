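"""Controlled-vocabulary standardization of measurement fields.

``measurementType``, ``measurementValue`` and ``measurementUnit`` are free
text; their ``...ID`` twins carry persistent URIs into controlled
vocabularies served by the NERC Vocabulary Server: Q01 (sampling instrument
and method attributes), P01 (parameter usage), P06 (units) and L22 (device
categories).  This module ships small offline subsets of those collections
as plain TSV files, fills the three ID columns from a label → URI mapping
table, and reports every label it could not map.

Matching is exact on normalized labels (trimmed, case-folded, internal
whitespace collapsed); there is no fuzzy matching, because a silent
mis-mapping is worse than an unmapped report line.  Live NVS lookups are an
extension point, not implemented here.
"""

from __future__ import annotations

import copy
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .errors import MalformedRowError
from .model import DatasetBundle, is_numeric_literal

__all__ = ["VocabularyEntry", "MappingTable", "StandardizationReport",
           "load_vocabulary", "load_mapping", "packaged_vocabularies",
           "default_mapping", "standardize", "resolve", "normalize_label"]

_WS = re.compile(r"\s+")

_COLLECTION_RE = re.compile(r"/collection/([A-Za-z0-9]+)/")

ROLES = ("type", "value", "unit")

_ID_FIELD = {"type": "measurementTypeID", "value": "measurementValueID",
             "unit": "measurementUnitID"}
_TEXT_FIELD = {"type": "measurementType", "value": "measurementValue",
               "unit": "measurementUnit"}


def normalize_label(label: str) -> str:
    """Trim, case-fold and collapse internal whitespace."""
    return _WS.sub(" ", label.strip()).casefold()


def _infer_collection(uri: str) -> str:
    match = _COLLECTION_RE.search(uri)
    if match and match.group(1) in ("Q01", "P01", "P06", "L22"):
        return match.group(1)
    return "other"


@dataclass(frozen=True)
class VocabularyEntry:
    """One concept from a controlled vocabulary."""

    uri: str
    preferred_label: str
    definition: str = ""
    usage_note: str = ""

    @property
    def collection(self) -> str:
        return _infer_collection(self.uri)


@dataclass
class MappingTable:
    """Free-text label → URI bindings, keyed by (role, normalized label)."""

    entries: dict[tuple[str, str], str] = field(default_factory=dict)

    def add(self, role: str, label: str, uri: str) -> None:
        if role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {role!r}")
        self.entries[(role, normalize_label(label))] = uri

    def lookup(self, role: str, label: str) -> str | None:
        return self.entries.get((role, normalize_label(label)))


@dataclass
class StandardizationReport:
    """What :func:`standardize` did: per-role counts of ID fields filled,
    distinct labels it could not map, and numeric values for which a
    value mapping existed but was (correctly) not applied."""

    filled: dict[str, int] = field(default_factory=lambda: dict.fromkeys(ROLES, 0))
    unmapped: dict[str, list[str]] = field(
        default_factory=lambda: {r: [] for r in ROLES})
    numeric_values_skipped: int = 0
    notes: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "filled": self.filled,
            "unmapped": self.unmapped,
            "numeric_values_skipped": self.numeric_values_skipped,
            "notes": self.notes,
        }, indent=2, sort_keys=True)


def _read_tsv(source) -> list[tuple[int, list[str]]]:
    """(line number, columns) pairs, header included; empty lines are
    dropped but keep their line numbers reserved."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    rows = []
    for n, line in enumerate(text.splitlines(), start=1):
        if line != "":
            rows.append((n, line.split("\t")))
    return rows


def load_vocabulary(source) -> list[VocabularyEntry]:
    """Parse a vocabulary TSV (columns: uri, preferred_label, definition,
    optional usage_note; one header line)."""
    rows = _read_tsv(source)
    entries = []
    for n, row in rows[1:]:
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            raise MalformedRowError(
                f"expected at least uri and preferred_label, got {row!r}", n)
        entries.append(VocabularyEntry(
            uri=row[0].strip(),
            preferred_label=row[1].strip(),
            definition=row[2].strip() if len(row) > 2 else "",
            usage_note=row[3].strip() if len(row) > 3 else ""))
    return entries


def load_mapping(source) -> MappingTable:
    """Parse a mapping TSV (columns: role, label, uri; one header line)."""
    rows = _read_tsv(source)
    table = MappingTable()
    for n, row in rows[1:]:
        if len(row) != 3:
            raise MalformedRowError(f"expected 3 columns, got {row!r}", n)
        role, label, uri = (c.strip() for c in row)
        if role not in ROLES:
            raise MalformedRowError(f"unknown role {role!r}", n)
        table.add(role, label, uri)
    return table


def _packaged(name: str):
    return (resources.files("obisenv") / "data" / name).open(
        "r", encoding="utf-8")


def packaged_vocabularies() -> list[VocabularyEntry]:
    """The offline Q01 + P06 + L22 subsets shipped with the package."""
    entries: list[VocabularyEntry] = []
    for name in ("q01.tsv", "p06.tsv", "l22.tsv"):
        with _packaged(name) as fh:
            entries.extend(load_vocabulary(fh))
    return entries


def default_mapping() -> MappingTable:
    """The packaged label → URI mapping covering the shipped subsets."""
    with _packaged("default_mapping.tsv") as fh:
        return load_mapping(fh)


def standardize(bundle: DatasetBundle, mapping: MappingTable | None = None,
                overwrite: bool = False
                ) -> tuple[DatasetBundle, StandardizationReport]:
    """Fill measurementTypeID/ValueID/UnitID from the mapping table.

    Only the three ID columns are touched — never free text, record counts
    or linkage fields.  An ID already present is kept unless *overwrite* is
    set.  ``measurementValueID`` is only ever filled when the value does
    NOT parse as a number: a URI identifies a fact (an instrument name, a
    life stage), not a quantity.  Returns a modified copy and a report;
    the operation is idempotent.
    """
    if mapping is None:
        mapping = default_mapping()
    out = copy.deepcopy(bundle)
    report = StandardizationReport()
    unmapped: dict[str, set[str]] = {r: set() for r in ROLES}

    for m in out.measurements:
        for role in ROLES:
            text = getattr(m, _TEXT_FIELD[role])
            if text == "":
                continue
            if role == "value" and is_numeric_literal(text):
                if (getattr(m, _ID_FIELD[role]) == ""
                        and mapping.lookup(role, text) is not None):
                    report.numeric_values_skipped += 1
                    report.notes.append(
                        f"numeric value {text!r} left without "
                        "measurementValueID (URIs identify facts, not "
                        "quantities)")
                continue
            if getattr(m, _ID_FIELD[role]) != "" and not overwrite:
                continue
            uri = mapping.lookup(role, text)
            if uri is None:
                unmapped[role].add(text)
            else:
                setattr(m, _ID_FIELD[role], uri)
                report.filled[role] += 1
        # a unit on a fact row (non-numeric value) is unusual but legal
        if (m.measurementUnit and m.measurementValue
                and not is_numeric_literal(m.measurementValue)):
            report.notes.append(
                f"INFO: unit {m.measurementUnit!r} present on fact row "
                f"({m.measurementType!r} = {m.measurementValue!r})")

    for role in ROLES:
        report.unmapped[role] = sorted(unmapped[role])
    return out, report


def resolve(uri: str,
            vocabularies: list[VocabularyEntry] | None = None
            ) -> VocabularyEntry | None:
    """Look a URI up in loaded vocabulary entries (offline; ``None`` when
    unknown)."""
    if vocabularies is None:
        vocabularies = packaged_vocabularies()
    for entry in vocabularies:
        if entry.uri == uri:
            return entry
    return None
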