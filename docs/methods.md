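# Methods

This note documents the data model, the rule semantics, the conversion
algorithms, the synthetic-data generators and the numerical/representation
choices made where the design was genuinely open.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Data model and absence

A dataset is a `DatasetBundle`: `EventRecord`s, `OccurrenceRecord`s,
`EMoFRecord`s and an EML metadata stub.  Absent values are `None` for
numeric fields and `""` for text fields; both serialize to the empty
string in tabular form and convert back losslessly.  Numbers are stored
as floats and rendered with the shortest decimal text that reads back to
the same float (`54.1 → "54.1"`, `51.0 → "51"`), so a write/read round
trip preserves values, though not necessarily the exact input spelling
(`"0.0000"` reads back as `0.0` and re-renders as `"0"`).

Identifier comparison is exact, case-sensitive string equality throughout.
Dates are stored verbatim and checked as ISO-8601 *syntax* only (reduced
precision, optional time and zone, intervals); no timezone normalization
is attempted.  The event `type` (level label) is free text; the
recommended values `cruise`/`station`/`sample`/`subsample` are advisory,
never enforced.

The eMoF record carries exactly fourteen columns.  The four terms it adds
over the classic MeasurementOrFact table (`occurrenceID`,
`measurementTypeID`, `measurementValueID`, `measurementUnitID`) are
registered with source `obis-emof` in the term registry; `occurrenceID`
keeps its ratified Darwin Core URI, the three `…ID` terms their
`rs.iobis.org` URIs.  An empty `occurrenceID` on a measurement *means*
event-level (abiotic or sampling attribute); this equivalence is relied on
everywhere.  `organismQuantity`/`organismQuantityType` are kept on
occurrence records because third-party archives use them, even though
quantifications belong in the eMoF; double encoding is a validator
warning (R8), not a modelling error.

## Archives

The descriptor (meta.xml) maps column indices to term URIs; the reader
joins extension rows to core rows through the positional id/coreid pair.
When an extension also maps an explicit `eventID` column, the explicit
value wins and a disagreement with the coreid is reported as an issue
rather than an error — both conventions occur in circulating archives.
Unresolvable coreids are likewise reported, not fatal, and surface later
as validator ERRORs.

Written archives are deterministic: fixed file names (`event.txt`,
`occurrence.txt`, `extendedmeasurementorfact.txt`), tab-delimited UTF-8
with one header line, canonical column order (dataclass fields, then
sorted extras), a fixed timestamp on zip members.  Identical bundles give
byte-identical zips, which the generator tests exploit.  The EML stub
round-trips title/abstract/creators only; full EML authoring is out of
scope.

## Validation

Eleven rules, three severities.  ERROR blocks conversion and writing;
WARNING and INFO never do — that enforcement split is this package's own
convention, the linkage semantics themselves are the standard's.  Notable
decisions:

- **R4** (a biotic row whose `eventID` differs from its occurrence's
  event) is an ERROR: the layout always places a biotic measurement under
  the same event as its occurrence, so a mismatch is treated as
  corruption, not design.
- **R6** (a `parentEventID` absent from the dataset) is only a WARNING:
  the ultimate parent (e.g. the cruise) may legitimately live in another
  archive.  `build_tree` still refuses such input, so conversions use a
  tolerant tree that treats cross-archive parents as roots.
- **R7** ("parses as a number") uses optional sign, decimal point and
  exponent; facts like `WP-2` or `alive` never trigger it.
- **R8** treats an eMoF row as a quantification when its normalized
  `measurementType` is in a small set (abundance, counts, biomass, cover)
  or equals the occurrence's `organismQuantityType`.
- All issues are collected (no fail-fast) so one report covers the whole
  archive.

`oracle_referential_check` re-implements R1–R5 with index-free nested list
scans, deliberately quadratic, as an independent oracle; the suite and the
acceptance script race it against `validate_bundle` on hundreds of
randomized bundles with injected defects.

## Hierarchy and inheritance

`resolve_inherited` returns the event's own value, else the nearest
ancestor's non-empty value.  Latitude and longitude resolve **as a pair
from the same ancestor**: walking the two fields independently could
combine a latitude from one level with a longitude from another,
fabricating a position that was never recorded.  Depth fields never
inherit — a CTD reading's depth must not be replaced by the cast's range —
so inheritance at flatten time is opt-in per field, defaulting to
`eventDate`, `decimalLatitude`, `decimalLongitude`, `footprintWKT`.

Hierarchical IDs join level labels with `:`.  Sorting such IDs
lexicographically reproduces a depth-first traversal *provided* sibling
labels are prefix-free and sort below the separator's code point where
they diverge; the generators use labels that satisfy this, and the
property test constructs its trees accordingly.  Sibling order is input
order; nothing is sorted implicitly.

## Layout conversions

`detect_option` classifies from content: no events → occurrence core
(layout 4 if `type="event"` rows without a `scientificName` are present,
else 1); events with an `occurrenceID`-bearing measurement table → 6;
events without one → 5 when one-to-one "dummy" wrappers (a childless
event with a parent, wrapping exactly one occurrence) are detected, else
2.  Dummy detection is necessarily heuristic — an actual one-organism
sample is indistinguishable from a dummy — and is documented as such; a
candidate wrapping two occurrences is an `AmbiguousDummyError`.

**6 → 1** dissolves events: event-level rows are duplicated onto every
occurrence of the event's *subtree* (a station-level temperature reaches
the occurrences of its child samples), and the metadata an occurrence
would otherwise inherit (date, coordinates as a pair, footprint, the
event's own depth range) is materialized onto each occurrence record.  An
event whose subtree holds measurements but no occurrence cannot be
represented in layout 1; with `allow_event_records` it becomes a
layout-4-style `type="event"` occurrence row instead of an error.

**1 → 6** groups occurrences into events by a configurable key tuple
(default: date, coordinates, depth range — the properties that distinguish
samples), names the events `sample1, sample2, …` in first-appearance
order (content-determined, no randomness), and collapses measurement rows
whose full content (ignoring identifiers) repeats identically across
*every* occurrence of an event into a single event-level row, layer by
layer.  Near-duplicates (e.g. differing remarks) are never collapsed —
lossless beats lossy.  A single-occurrence event is genuinely ambiguous:
its shared rows are indistinguishable from organism-level ones, so they
keep their `occurrenceID` (again the lossless choice); consequently the
"n·m collapses to m" inversion holds for events with ≥ 2 occurrences,
while conservation of the implied occurrence–measurement multiset holds
always.  That multiset — occurrence-level rows paired with their
organism, event-level rows implying one pair per occurrence of the event —
is the conversion invariant; the raw row multiset cannot be, since
duplication is precisely what the conversions add or remove.

**5 → 6** deletes each dummy, re-links its occurrence to the dummy's
parent and moves the dummy's measurements onto the occurrence as biotic
rows.  Bundles already in layout 6 (or 2, which imports as 6 with an
empty `occurrenceID` column) pass through unchanged.

`flatten` requires zero ERROR issues and emits exactly one row per
measurement, ordered by event path then occurrenceID, with inherited
fields resolved as above.

## Synthetic generators

The generators emulate the four structural families of combined datasets
plus the multi-gear scenario; all draw values from fixed plausible ranges
with a `random.Random(seed)` generator.  Same spec ⇒ identical bundle ⇒
byte-identical archive.  What they emulate is **structure and linkage**:
hierarchy shapes, which rows carry which identifiers, where facts and
measurements attach.  What they do not emulate: oceanographic physics,
real taxonomic composition, instrument error, or the actual pilot
datasets' values — so passing tests demonstrate structural conformance
machinery, not scientific fidelity of values.

- *sample_based / fig1*: cruise → stations → Van Veen grab and
  multi-corer (point coordinates) and beam trawl (LINESTRING footprint) →
  core slices; macrobenthos on the grab, meiofauna on slices, sediment
  measurements at sample/subsample level, the gear as a
  sampling-attribute fact.
- *ctd*: one cast; each reading depth is a child event with one
  temperature and one salinity row (min = max depth); Niskin bottles are
  further children with water-sample measurements and plankton counts; a
  derived surface temperature sits at cast level.
- *telemetry*: capture (occurrence + biometrics linked by both IDs),
  tracking sections each linked to an occurrence of the animal, GPS
  position children with coordinates and abiotic rows but never an
  occurrence, and a recovery event.  `positions` is the total across the
  track, distributed evenly (remainder to the first sections); the
  section grouping criterion in the wild is loosely "same period and
  area", here fixed-size position blocks.  Tag-detection datasets reuse
  this generator with sections as receiver-window groupings.
- *vpr*: a tow with one section event per full software-grouping interval
  (`floor(duration/interval)`); a trailing partial interval becomes one
  extra section flagged in `eventRemarks` rather than being dropped; the
  frame rate (default 30 frames/s) is a fact on the tow; optionally a raw
  CTD chain hangs off the tow.

`registry()` maps the 13 pilot-dataset archetypes onto these categories
with per-archetype seeds and content kinds (abundance / biomass /
biometrics / presence; abiotic on or off).  Default sizes are small
(stations = 2, depths = 20, positions = 20) so the full sweep, the
500-bundle validator race and the 200-instance conversion property all
run in seconds.

## Vocabulary standardization

Matching free text to URIs is exact on normalized labels (trim,
case-fold, collapse internal whitespace); there is no fuzzy matching,
because a silent mis-mapping is worse than an unmapped report line.  URIs
are stored exactly as given, trailing slash preserved.
`measurementValueID` is only ever filled for non-numeric values; a
numeric value with an applicable mapping is skipped and noted in the
report.  A unit present on a fact row is surfaced as an informational
note only.  The packaged vocabulary subsets (Q01 sampling attributes, a
few P06 units, the WP-2 entry of L22) ship as plain TSV; live NERC
Vocabulary Server lookups are an extension point, deliberately not
implemented (everything works offline).

## Known limitations

- Layout 3 (one logical dataset split over two linked archives) is
  detect-out-of-scope entirely; layouts 2 and 5 are read/detect-only as
  write targets.
- Dummy-event detection (layout 5) and event reconstruction (1 → 6) are
  heuristic by necessity; both are deterministic and documented, but
  pathological inputs (a real one-organism sample; occurrences sharing a
  key tuple across genuinely different samples) will be grouped by the
  rule, not by the unknowable truth.
- The validator checks structure, not science: no temperature ranges, no
  on-land tests, no taxonomic name resolution.
- Streaming parsing of multi-gigabyte archives is not attempted; tables
  are read into memory.
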