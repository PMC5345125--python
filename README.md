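# obisenv

Darwin Core Archives for **combined biological and environmental marine
data**: a data model, reader/writer, validator, layout converter,
vocabulary standardizer and synthetic-dataset generator for the Event Core
+ Occurrence extension + **ExtendedMeasurementOrFact (eMoF)** archive
layout used by OBIS.

## The problem

Marine surveys rarely produce species occurrences alone.  A benthic grab
comes with sediment grain sizes; a plankton tow with net mesh size and
filtered volume; a CTD cast with hundreds of temperature/salinity
readings; a tagged gull with thousands of GPS positions and the biometrics
taken at capture.  A classic occurrence-centred Darwin Core Archive cannot
hold these: sample-level measurements must be duplicated onto every
organism, organism-level measurements have nowhere to go, and a sample
with no organisms cannot be recorded at all.

The layout this package implements solves that with three pieces:

- **Event Core** — the sampling event (cruise, station visit, gear
  deployment, core slice) is the central record, and `parentEventID`
  builds a hierarchy (`cruise1:station5:grab1`) so coordinates, dates and
  depths are stored once, at the level where they were determined.
- **Occurrence extension** — taxon observations, each linked to exactly
  one event.
- **eMoF extension** — the MeasurementOrFact table plus four terms:
  `occurrenceID` cross-links a *biotic* measurement (body length,
  abundance) to its organism, while *abiotic* measurements and sampling
  attributes carry only an `eventID`; `measurementTypeID`,
  `measurementValueID` and `measurementUnitID` hold controlled-vocabulary
  URIs (NERC collections Q01 for sampling attributes, P06 for units, L22
  for devices) so that free-text fields become machine-comparable.

The package is a library first (`import obisenv`), with narrative scripts
under `examples/` and a thin `obisenv` command-line tool.

## A worked example

`examples/standardize_vocabulary.py` builds three sampling-attribute rows
for a WP-2 plankton net and fills their vocabulary URIs from the packaged
offline Q01/P06/L22 subsets:

```
Net diameter = 50 cm
  typeID : http://vocab.nerc.ac.uk/collection/Q01/current/Q0100012/
  unitID : http://vocab.nerc.ac.uk/collection/P06/current/ULCM/
Net mesh size = 200 um
  typeID : http://vocab.nerc.ac.uk/collection/Q01/current/Q0100015/
  unitID : http://vocab.nerc.ac.uk/collection/P06/current/UMIC/
Sampling gear name = WP-2
  typeID : http://vocab.nerc.ac.uk/collection/Q01/current/Q0100002/
  valueID: http://vocab.nerc.ac.uk/collection/L22/current/NETT0168/  (WP-2 net)

filled per role: {'type': 3, 'value': 1, 'unit': 2} (type/unit URIs for all rows; a value URI only for the fact)
```

The numeric values `50` and `200` deliberately receive **no**
`measurementValueID` — a URI identifies a concept (the WP-2 net), not a
quantity.  `examples/convert_layouts.py` shows the other core idea, the
duplication an occurrence-core layout forces:

```
event-core bundle : 2 events, 9 occurrences, 6 event-level + 9 biotic rows
occurrence core   : 35 measurement rows (each shared row duplicated per organism), layout detected: 1
rebuilt event core: 2 events, 6 event-level rows restored, layout detected: 6
```

Six shared measurements become 26 duplicated copies in the occurrence
core (plus the 9 biotic rows); rebuilding the events collapses them back
to 6.

The other examples generate a CTD archive and round-trip it through a
zip, validate a hand-built bundle, and flatten the multi-gear hierarchy
into an analysis table.  The command-line tool offers the same
operations over archive files:

```sh
obisenv generate --category ctd --seed 7 -o ctd.zip
obisenv validate ctd.zip
obisenv info ctd.zip
obisenv flatten ctd.zip -o ctd.tsv
obisenv standardize ctd.zip -o ctd-std.zip --report report.json
obisenv convert ctd.zip --to 1 --allow-event-records -o occ.zip
```

## Layout conversions, briefly

| layout | shape | support |
|---|---|---|
| 1 | occurrence core + measurements (everything duplicated) | read, write, ↔ 6 |
| 2 | event core + occurrences + measurements without `occurrenceID` | read/detect (imports as 6) |
| 4 | occurrence core with `type="event"` rows standing in for events | read, write (from 6) |
| 5 | event core with one-to-one "dummy" events wrapping occurrences | read/detect, → 6 |
| 6 | event core + occurrence extension + eMoF | native |

Layout 3 (one dataset split across two linked archives) is out of scope.
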