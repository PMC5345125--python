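uri	preferred_label	definition	usage_note
http://vocab.nerc.ac.uk/collection/P06/current/ULCM/	Centimetres	Unit of length equal to one hundredth of a metre.
http://vocab.nerc.ac.uk/collection/P06/current/UMIC/	Micrometres	Unit of length equal to one millionth of a metre.
http://vocab.nerc.ac.uk/collection/P06/current/ULAA/	Metres	SI base unit of length.
http://vocab.nerc.ac.uk/collection/P06/current/UPAA/	Degrees Celsius	Unit of temperature on the Celsius scale.
http://vocab.nerc.ac.uk/collection/P06/current/UUUU/	Dimensionless	Quantity expressed without a unit.
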