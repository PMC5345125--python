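"""Fill controlled-vocabulary URIs into free-text measurement fields.

Three sampling-attribute rows for a WP-2 plankton net: the net diameter
(50 cm), the mesh size (200 um) and the gear name itself.  Standardization
fills measurementTypeID from Q01 (sampling attributes), measurementUnitID
from P06 (units) and — only for the non-numeric fact "WP-2" —
measurementValueID from L22 (device categories).  Numeric values never
get a valueID: a URI identifies a concept, not a quantity.
"""

from obisenv.model import DatasetBundle, make_record
from obisenv.vocab import resolve, standardize

rows = [
    {"eventID": "tow1", "measurementType": "Net diameter",
     "measurementValue": "50", "measurementUnit": "cm"},
    {"eventID": "tow1", "measurementType": "Net mesh size",
     "measurementValue": "200", "measurementUnit": "um"},
    {"eventID": "tow1", "measurementType": "Sampling gear name",
     "measurementValue": "WP-2"},
]
bundle = DatasetBundle(measurements=[make_record("emof", r) for r in rows])

standardized, report = standardize(bundle)
for m in standardized.measurements:
    print(f"{m.measurementType} = {m.measurementValue} "
          f"{m.measurementUnit}".rstrip())
    print(f"  typeID : {m.measurementTypeID}")
    if m.measurementValueID:
        entry = resolve(m.measurementValueID)
        print(f"  valueID: {m.measurementValueID}  "
              f"({entry.preferred_label})")
    if m.measurementUnitID:
        print(f"  unitID : {m.measurementUnitID}")

print(f"\nfilled per role: {report.filled} "
      "(type/unit URIs for all rows; a value URI only for the fact)")
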