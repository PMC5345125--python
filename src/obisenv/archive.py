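"""Darwin Core Archive packaging: meta.xml descriptors, data tables, zips.

A Darwin Core Archive is a zip holding a descriptor (``meta.xml``) that maps
column indices of delimited text tables onto term URIs, one core table (the
centre of the star schema), extension tables joined to the core through a
positional id/coreid pair, and an EML metadata document.  This module reads
archives in any supported layout and writes the three layouts the package
targets (occurrence core with measurements: layouts 1 and 4; event core with
occurrence and eMoF extensions: layout 6).

Defaults follow common GBIF practice: tab-delimited UTF-8 tables with one
header line.  Written file names are fixed (``event.txt``,
``occurrence.txt``, ``extendedmeasurementorfact.txt``) for determinism.
"""

from __future__ import annotations

import csv
import io
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from . import terms as T
from .errors import (DuplicateCoreError, LayoutMismatchError,
                     MalformedXMLError, MissingDataFileError,
                     MissingDescriptorError, UnknownRowTypeError,
                     UnknownTermError)
from .model import (DatasetBundle, EmlStub, EMOF_FIELDS, EVENT_FIELDS,
                    OCCURRENCE_FIELDS, get_field, make_record)
from .validation import ValidationIssue

__all__ = ["ArchiveDescriptor", "ExtensionDescriptor", "parse_descriptor",
           "serialize_descriptor", "read_archive", "write_archive"]

DWCA_NS = "http://rs.tdwg.org/dwc/text/"

_ROWTYPE_TO_KIND = {
    T.EVENT_ROWTYPE: "event",
    T.OCCURRENCE_ROWTYPE: "occurrence",
    T.EMOF_ROWTYPE: "emof",
    T.MOF_ROWTYPE: "mof",
}
_KIND_TO_ROWTYPE = {v: k for k, v in _ROWTYPE_TO_KIND.items()}

# reverse URI -> label map over the registry
_URI_TO_NAME = {}
for _name in T.known_terms():
    _URI_TO_NAME.setdefault(T.term_info(_name).uri, _name)


@dataclass(frozen=True)
class ExtensionDescriptor:
    row_type: str                 # occurrence | emof | mof
    filename: str
    coreid_column: int
    fields: tuple[tuple[str, int], ...]  # (term label, column index)


@dataclass(frozen=True)
class ArchiveDescriptor:
    """Parsed meta.xml: where each table lives and what its columns mean."""

    core_row_type: str            # event | occurrence
    core_file: str
    core_id_column: int
    core_fields: tuple[tuple[str, int], ...]
    extensions: tuple[ExtensionDescriptor, ...] = ()
    delimiter: str = "\t"
    encoding: str = "UTF-8"
    header_lines: int = 1


def _term_name_from_uri(uri: str) -> str:
    if uri in _URI_TO_NAME:
        return _URI_TO_NAME[uri]
    tail = uri.rstrip("/").rsplit("/", 1)[-1]
    if tail in T.known_terms():
        return tail
    raise UnknownTermError(uri)


def _unescape_delim(text: str, default: str) -> str:
    if not text:
        return default
    return (text.replace("\\t", "\t").replace("\\n", "\n")
                .replace("\\r", "\r"))


def _parse_table_element(el) -> tuple[str, int, tuple[tuple[str, int], ...]]:
    loc = el.findtext(f"{{{DWCA_NS}}}files/{{{DWCA_NS}}}location")
    if loc is None:
        loc = el.findtext("files/location")  # tolerate missing namespace
    if not loc:
        raise MalformedXMLError("table element without <files><location>")
    id_el = el.find(f"{{{DWCA_NS}}}id")
    if id_el is None:
        id_el = el.find(f"{{{DWCA_NS}}}coreid")
    if id_el is None:
        id_el = el.find("id") if el.find("id") is not None else el.find("coreid")
    id_col = int(id_el.get("index")) if id_el is not None else 0
    mapped: list[tuple[str, int]] = []
    seen_idx: set[int] = set()
    for f in el.iter(f"{{{DWCA_NS}}}field"):
        idx = int(f.get("index"))
        if idx in seen_idx:
            raise MalformedXMLError(f"duplicate column index {idx} in {loc}")
        seen_idx.add(idx)
        mapped.append((_term_name_from_uri(f.get("term")), idx))
    return loc, id_col, tuple(mapped)


def parse_descriptor(descriptor_text: str | bytes) -> ArchiveDescriptor:
    """Parse meta.xml text into an :class:`ArchiveDescriptor`."""
    if isinstance(descriptor_text, str):
        descriptor_text = descriptor_text.encode("utf-8")
    try:
        root = etree.fromstring(descriptor_text)
    except etree.XMLSyntaxError as exc:
        raise MalformedXMLError(str(exc)) from None

    cores = root.findall(f"{{{DWCA_NS}}}core") + root.findall("core")
    if len(cores) > 1:
        raise DuplicateCoreError(
            "descriptor declares more than one core; the star schema has "
            "exactly one centre")
    if not cores:
        raise MalformedXMLError("descriptor has no <core> element")
    core = cores[0]

    row_type = core.get("rowType", "")
    if row_type not in (T.EVENT_ROWTYPE, T.OCCURRENCE_ROWTYPE):
        raise UnknownRowTypeError(f"unsupported core rowType {row_type!r}")
    delimiter = _unescape_delim(core.get("fieldsTerminatedBy", ""), "\t")
    encoding = core.get("encoding", "UTF-8")
    header = int(core.get("ignoreHeaderLines", "1"))
    core_file, core_id, core_fields = _parse_table_element(core)

    extensions: list[ExtensionDescriptor] = []
    for ext in (root.findall(f"{{{DWCA_NS}}}extension")
                + root.findall("extension")):
        ext_rt = ext.get("rowType", "")
        if ext_rt not in _ROWTYPE_TO_KIND or ext_rt == T.EVENT_ROWTYPE:
            raise UnknownRowTypeError(
                f"unsupported extension rowType {ext_rt!r}")
        fname, coreid, mapped = _parse_table_element(ext)
        extensions.append(ExtensionDescriptor(
            _ROWTYPE_TO_KIND[ext_rt], fname, coreid, mapped))

    return ArchiveDescriptor(
        core_row_type=_ROWTYPE_TO_KIND[row_type],
        core_file=core_file, core_id_column=core_id,
        core_fields=core_fields, extensions=tuple(extensions),
        delimiter=delimiter, encoding=encoding, header_lines=header)


def _escape_delim(delim: str) -> str:
    return delim.replace("\t", "\\t").replace("\n", "\\n")


def serialize_descriptor(descriptor: ArchiveDescriptor) -> str:
    """Render a descriptor back to meta.xml; inverse of parse_descriptor."""
    nsmap = {None: DWCA_NS}
    root = etree.Element(f"{{{DWCA_NS}}}archive", nsmap=nsmap,
                         metadata="eml.xml")

    def table(tag: str, row_type: str, fname: str, id_tag: str,
              id_col: int, mapped) -> etree._Element:
        el = etree.SubElement(
            root, f"{{{DWCA_NS}}}{tag}",
            rowType=_KIND_TO_ROWTYPE[row_type],
            encoding=descriptor.encoding,
            fieldsTerminatedBy=_escape_delim(descriptor.delimiter),
            linesTerminatedBy="\\n", fieldsEnclosedBy="",
            ignoreHeaderLines=str(descriptor.header_lines))
        files = etree.SubElement(el, f"{{{DWCA_NS}}}files")
        etree.SubElement(files, f"{{{DWCA_NS}}}location").text = fname
        etree.SubElement(el, f"{{{DWCA_NS}}}{id_tag}", index=str(id_col))
        for term, idx in mapped:
            etree.SubElement(el, f"{{{DWCA_NS}}}field", index=str(idx),
                             term=T.term_info(term).uri)
        return el

    table("core", descriptor.core_row_type, descriptor.core_file, "id",
          descriptor.core_id_column, descriptor.core_fields)
    for ext in descriptor.extensions:
        table("extension", ext.row_type, ext.filename, "coreid",
              ext.coreid_column, ext.fields)
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------

class _Source:
    """Uniform file access over a zip archive or an unpacked directory."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._zip = None
        if self.path.is_file():
            try:
                self._zip = zipfile.ZipFile(self.path)
            except zipfile.BadZipFile as exc:
                raise MalformedXMLError(f"not a zip archive: {exc}") from None

    def read(self, name: str) -> bytes:
        if self._zip is not None:
            try:
                return self._zip.read(name)
            except KeyError:
                raise MissingDataFileError(name) from None
        member = self.path / name
        if not member.exists():
            raise MissingDataFileError(str(member))
        return member.read_bytes()

    def has(self, name: str) -> bool:
        if self._zip is not None:
            return name in self._zip.namelist()
        return (self.path / name).exists()


def _read_rows(raw: bytes, descriptor: ArchiveDescriptor) -> list[list[str]]:
    text = raw.decode(descriptor.encoding)
    reader = csv.reader(io.StringIO(text), delimiter=descriptor.delimiter,
                        quoting=csv.QUOTE_NONE, quotechar=None)
    rows = [row for row in reader if row]
    return rows[descriptor.header_lines:]


def _row_fields(row: list[str], mapped) -> dict[str, str]:
    out = {}
    for term, idx in mapped:
        out[term] = row[idx] if idx < len(row) else ""
    return out


def read_archive(path: str | Path,
                 issues: list[ValidationIssue] | None = None
                 ) -> DatasetBundle:
    """Read a DwC-A zip (or unpacked directory) into a
    :class:`DatasetBundle`.

    Extension rows are joined to core rows through the descriptor's
    positional id/coreid pair; when an extension also maps an explicit
    ``eventID`` column, the explicit value wins and a disagreement with the
    coreid is reported into *issues* (not fatal).  Unresolvable coreids are
    likewise reported and surface later as validator ERRORs.
    """
    src = _Source(path)
    if not src.has("meta.xml"):
        raise MissingDescriptorError(f"no meta.xml in {path}")
    descriptor = parse_descriptor(src.read("meta.xml"))
    sink = issues if issues is not None else []

    bundle = DatasetBundle(emof_has_occurrence_id=False)
    core_rows = _read_rows(src.read(descriptor.core_file), descriptor)
    core_ids: list[str] = []
    for row in core_rows:
        fields = _row_fields(row, descriptor.core_fields)
        cid = (row[descriptor.core_id_column]
               if descriptor.core_id_column < len(row) else "")
        core_ids.append(cid)
        if descriptor.core_row_type == "event":
            fields.setdefault("eventID", cid)
            bundle.events.append(make_record("event", fields))
        else:
            fields.setdefault("occurrenceID", cid)
            bundle.occurrences.append(make_record("occurrence", fields))
    known_core_ids = set(core_ids)

    for ext in descriptor.extensions:
        rows = _read_rows(src.read(ext.filename), descriptor)
        for n, row in enumerate(rows, start=1):
            fields = _row_fields(row, ext.fields)
            coreid = (row[ext.coreid_column]
                      if ext.coreid_column < len(row) else "")
            if coreid and coreid not in known_core_ids:
                sink.append(ValidationIssue(
                    "R1" if descriptor.core_row_type == "event" else "R2",
                    "ERROR", ext.row_type, f"{ext.filename} row {n}",
                    f"coreid {coreid!r} not found in core table"))
            if ext.row_type == "occurrence":
                explicit = fields.get("eventID", "")
                if explicit and coreid and explicit != coreid:
                    sink.append(ValidationIssue(
                        "R3", "WARNING", "occurrence",
                        f"{ext.filename} row {n}",
                        f"explicit eventID {explicit!r} disagrees with "
                        f"coreid {coreid!r}; explicit value kept"))
                fields["eventID"] = explicit or coreid
                bundle.occurrences.append(make_record("occurrence", fields))
            else:  # emof | mof
                if any(term == "occurrenceID" for term, _ in ext.fields):
                    bundle.emof_has_occurrence_id = True
                link = "eventID" if descriptor.core_row_type == "event" \
                    else "occurrenceID"
                explicit = fields.get(link, "")
                if explicit and coreid and explicit != coreid:
                    sink.append(ValidationIssue(
                        "R1", "WARNING", "emof", f"{ext.filename} row {n}",
                        f"explicit {link} {explicit!r} disagrees with "
                        f"coreid {coreid!r}; explicit value kept"))
                fields[link] = explicit or coreid
                bundle.measurements.append(make_record("emof", fields))

    if src.has("eml.xml"):
        bundle.metadata = _parse_eml(src.read("eml.xml"))

    from .options import detect_option  # deferred: options depends on model
    bundle.schema_option = detect_option(bundle)
    return bundle


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

_DATA_FILES = {"event": "event.txt", "occurrence": "occurrence.txt",
               "emof": "extendedmeasurementorfact.txt"}
# fixed timestamp inside written zips so identical content gives
# identical bytes
_ZIP_DATE = (2017, 1, 17, 0, 0, 0)


def _columns(records, canonical) -> list[str]:
    cols = list(canonical)
    extra = sorted({k for r in records
                    for k in getattr(r, "extras", {})})
    return cols + extra


def _table_text(records, columns, delimiter: str) -> str:
    lines = [delimiter.join(columns)]
    for r in records:
        lines.append(delimiter.join(get_field(r, c) for c in columns))
    return "\n".join(lines) + "\n"


def _parse_eml(raw: bytes) -> EmlStub:
    try:
        root = etree.fromstring(raw)
    except etree.XMLSyntaxError:
        return EmlStub()
    title = root.findtext(".//title") or ""
    abstract = root.findtext(".//abstract/para") or ""
    creators = tuple(
        el.text for el in root.findall(".//creator/individualName/surName")
        if el.text)
    return EmlStub(title=title, abstract=abstract, creators=creators)


def _eml_text(meta: EmlStub) -> str:
    root = etree.Element("eml")
    ds = etree.SubElement(root, "dataset")
    etree.SubElement(ds, "title").text = meta.title
    for name in meta.creators:
        creator = etree.SubElement(ds, "creator")
        ind = etree.SubElement(creator, "individualName")
        etree.SubElement(ind, "surName").text = name
    abstract = etree.SubElement(ds, "abstract")
    etree.SubElement(abstract, "para").text = meta.abstract
    return etree.tostring(root, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode("utf-8")


def _build_descriptor_for_layout(bundle: DatasetBundle,
                                 layout: int) -> ArchiveDescriptor:
    delim = "\t"
    if layout == 6:
        ev_cols = _columns(bundle.events, EVENT_FIELDS)
        occ_cols = _columns(bundle.occurrences, OCCURRENCE_FIELDS)
        emof_cols = list(EMOF_FIELDS)
        return ArchiveDescriptor(
            core_row_type="event", core_file=_DATA_FILES["event"],
            core_id_column=0,
            core_fields=tuple((c, i) for i, c in enumerate(ev_cols)),
            extensions=(
                ExtensionDescriptor(
                    "occurrence", _DATA_FILES["occurrence"], 1,
                    tuple((c, i) for i, c in enumerate(occ_cols))),
                ExtensionDescriptor(
                    "emof", _DATA_FILES["emof"], 0,
                    tuple((c, i) for i, c in enumerate(emof_cols))),
            ),
            delimiter=delim)
    # layouts 1 and 4: occurrence core + eMoF keyed on occurrenceID
    occ_cols = _columns(bundle.occurrences, OCCURRENCE_FIELDS)
    emof_cols = list(EMOF_FIELDS)
    return ArchiveDescriptor(
        core_row_type="occurrence", core_file=_DATA_FILES["occurrence"],
        core_id_column=0,
        core_fields=tuple((c, i) for i, c in enumerate(occ_cols)),
        extensions=(
            ExtensionDescriptor(
                "emof", _DATA_FILES["emof"], 2,
                tuple((c, i) for i, c in enumerate(emof_cols))),
        ),
        delimiter=delim)


def write_archive(bundle: DatasetBundle, path: str | Path,
                  layout: int = 6) -> Path:
    """Write *bundle* as a DwC-A zip in the given layout (1, 4 or 6).

    Layout 6 is the recommended structure: Event core + Occurrence
    extension + eMoF extension.  Layouts 1 and 4 use an Occurrence core
    with the measurements keyed on occurrenceID; convert first (module
    :mod:`obisenv.options`) if the bundle is in a different shape.
    Re-reading the written archive yields an equal bundle up to canonical
    ordering.
    """
    if layout not in (1, 4, 6):
        raise LayoutMismatchError(f"unsupported write layout {layout}")
    if layout == 6:
        if bundle.occurrences and not bundle.events:
            raise LayoutMismatchError(
                "layout 6 needs an Event core but the bundle has no "
                "events; convert with option1_to_option6 first")
        for m in bundle.measurements:
            if not m.eventID:
                raise LayoutMismatchError(
                    "layout 6 requires every measurement to carry an "
                    "eventID")
    else:
        if bundle.events:
            raise LayoutMismatchError(
                f"layout {layout} uses an Occurrence core but the bundle "
                "has events; convert with option6_to_option1 first")
        for m in bundle.measurements:
            if not m.occurrenceID:
                raise LayoutMismatchError(
                    f"layout {layout} requires every measurement to carry "
                    "an occurrenceID")

    descriptor = _build_descriptor_for_layout(bundle, layout)
    delim = descriptor.delimiter

    members: list[tuple[str, str]] = [
        ("meta.xml", serialize_descriptor(descriptor)),
        ("eml.xml", _eml_text(bundle.metadata)),
    ]
    if layout == 6:
        ev_cols = [c for c, _ in descriptor.core_fields]
        occ_ext, emof_ext = descriptor.extensions
        occ_cols = [c for c, _ in occ_ext.fields]
        emof_cols = [c for c, _ in emof_ext.fields]
        members.append((descriptor.core_file,
                        _table_text(bundle.events, ev_cols, delim)))
        members.append((occ_ext.filename,
                        _table_text(bundle.occurrences, occ_cols, delim)))
        members.append((emof_ext.filename,
                        _table_text(bundle.measurements, emof_cols, delim)))
    else:
        occ_cols = [c for c, _ in descriptor.core_fields]
        emof_ext = descriptor.extensions[0]
        emof_cols = [c for c, _ in emof_ext.fields]
        members.append((descriptor.core_file,
                        _table_text(bundle.occurrences, occ_cols, delim)))
        members.append((emof_ext.filename,
                        _table_text(bundle.measurements, emof_cols, delim)))

    path = Path(path)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, text in members:
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o644 << 16
            zf.writestr(info, text)
    return path
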