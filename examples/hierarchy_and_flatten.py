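"""Walk the multi-gear sampling hierarchy and flatten it for analysis.

The scenario: one cruise, one station, three gear deployments (Van Veen
grab, beam trawl, multi-corer) and core slices below the corer — a
four-level hierarchy in which coordinates and dates live at the level
where they were determined.  Flattening produces one row per measurement
with the inherited metadata resolved, which is what an analyst wants to
load into a data frame.
"""

from obisenv import fixtures
from obisenv.hierarchy import annotate_levels, build_tree
from obisenv.options import flatten

bundle = fixtures.generate(fixtures.ScenarioSpec(category="fig1", seed=5,
                                                 stations=1))
tree = build_tree(bundle.events)
levels = annotate_levels(tree, ["cruise", "station", "sample",
                                "subsample"])

print(f"{len(tree.nodes)} events over {tree.max_depth()} levels:")
for eid in sorted(tree.nodes):
    print(f"  {levels[eid]:<10} {eid}")

rows = flatten(bundle)
print(f"\nflattened to {len(rows)} measurement rows "
      "(one per eMoF record); a sediment example:")
row = next(r for r in rows
           if r.measurement.measurementType == "Organic carbon content")
print(f"  path      : {' > '.join(row.event_path)}")
print(f"  inherited : date={row.eventDate} "
      f"lat={row.decimalLatitude} lon={row.decimalLongitude}")
print(f"  value     : {row.measurement.measurementValue} "
      f"{row.measurement.measurementUnit} "
      "(coordinates inherited from the corer deployment — the nearest "
      "ancestor that recorded a position — not stored on the slice)")
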