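"""Generate a synthetic CTD dataset and round-trip it through a zip.

A CTD cast is modelled as one parent event whose children are the reading
depths (each holding a temperature and a salinity row) and the Niskin
bottles (water samples with plankton counts).  The archive written here is
a complete Darwin Core Archive: meta.xml descriptor, EML stub and three
tab-separated tables.  Re-reading it must give back the same dataset —
that equality is printed last.
"""

import tempfile
from pathlib import Path

from obisenv import archive, fixtures

spec = fixtures.ScenarioSpec(category="ctd", seed=7, depths=25, niskins=3)
bundle = fixtures.generate(spec)

cast = next(e for e in bundle.events if e.type == "cast")
children = [e for e in bundle.events if e.parentEventID == cast.eventID]
print(f"cast {cast.eventID!r} at ({cast.decimalLatitude}, "
      f"{cast.decimalLongitude}) with {len(children)} child events "
      f"({spec.depths} reading depths + {spec.niskins} Niskin bottles)")
print(f"occurrences: {len(bundle.occurrences)}  "
      f"measurements: {len(bundle.measurements)}")

with tempfile.TemporaryDirectory() as tmp:
    path = archive.write_archive(bundle, Path(tmp) / "ctd.zip", layout=6)
    print(f"wrote {path.name}: {path.stat().st_size} bytes")
    again = archive.read_archive(path)
    print("read-back equals original:",
          again.sorted_copy() == bundle.sorted_copy())
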