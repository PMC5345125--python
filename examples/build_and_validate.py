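"""Build a tiny combined dataset by hand and validate its linkage.

One plankton-net haul (an event) with two copepod occurrences: the tow's
sampling attributes are event-level eMoF rows (no occurrenceID), the
abundances are biotic rows carrying both the eventID and an occurrenceID.
The validator's report should be free of ERROR issues; the INFO lines
point out free-text terms that still lack vocabulary URIs.
"""

from obisenv.model import DatasetBundle, make_record
from obisenv.validation import issues_to_text, validate_bundle

event = make_record("event", {
    "eventID": "cruise7:station2:tow1",
    "parentEventID": "",
    "eventDate": "2016-05-12",
    "decimalLatitude": "51.52",
    "decimalLongitude": "2.93",
    "minimumDepthInMeters": "0",
    "maximumDepthInMeters": "40",
    "samplingProtocol": "vertical WP-2 haul",
})

occurrences = [
    make_record("occurrence", {"occurrenceID": "tow1-o1",
                               "eventID": event.eventID,
                               "scientificName": "Calanus finmarchicus"}),
    make_record("occurrence", {"occurrenceID": "tow1-o2",
                               "eventID": event.eventID,
                               "scientificName": "Temora longicornis"}),
]

measurements = [
    # sampling attributes: event-level, occurrenceID stays empty
    make_record("emof", {"eventID": event.eventID,
                         "measurementType": "Sampling gear name",
                         "measurementValue": "WP-2"}),
    make_record("emof", {"eventID": event.eventID,
                         "measurementType": "Net mesh size",
                         "measurementValue": "200",
                         "measurementUnit": "um"}),
    # biotic rows: linked to both the event and the organism
    make_record("emof", {"eventID": event.eventID,
                         "occurrenceID": "tow1-o1",
                         "measurementType": "Abundance",
                         "measurementValue": "431",
                         "measurementUnit":
                             "individuals per cubic metre"}),
    make_record("emof", {"eventID": event.eventID,
                         "occurrenceID": "tow1-o2",
                         "measurementType": "Abundance",
                         "measurementValue": "112",
                         "measurementUnit":
                             "individuals per cubic metre"}),
]

bundle = DatasetBundle(events=[event], occurrences=occurrences,
                       measurements=measurements)
issues = validate_bundle(bundle)
print(issues_to_text(issues))
print()
print(f"events={len(bundle.events)} occurrences={len(bundle.occurrences)} "
      f"measurements={len(bundle.measurements)}")
print("ERROR issues:", sum(i.severity == "ERROR" for i in issues),
      "(0 means the archive is structurally sound and publishable)")
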