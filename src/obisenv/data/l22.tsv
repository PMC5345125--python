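uri	preferred_label	definition	usage_note
http://vocab.nerc.ac.uk/collection/L22/current/NETT0168/	WP-2 net	A 57 cm diameter ring net with 200 micrometre mesh designed for standard vertical zooplankton hauls.
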