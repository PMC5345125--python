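role	label	uri
type	Net diameter	http://vocab.nerc.ac.uk/collection/Q01/current/Q0100012/
type	Net mesh size	http://vocab.nerc.ac.uk/collection/Q01/current/Q0100015/
type	Sampling gear name	http://vocab.nerc.ac.uk/collection/Q01/current/Q0100002/
type	Sampling instrument name	http://vocab.nerc.ac.uk/collection/Q01/current/Q0100002/
type	Sampling device aperture diameter	http://vocab.nerc.ac.uk/collection/Q01/current/Q0100012/
type	Sampling device aperture width	http://vocab.nerc.ac.uk/collection/Q01/current/Q0100013/
type	Sampling device aperture length	http://vocab.nerc.ac.uk/collection/Q01/current/Q0100014/
type	Sampling net mesh size	http://vocab.nerc.ac.uk/collection/Q01/current/Q0100015/
value	WP-2	http://vocab.nerc.ac.uk/collection/L22/current/NETT0168/
unit	cm	http://vocab.nerc.ac.uk/collection/P06/current/ULCM/
unit	um	http://vocab.nerc.ac.uk/collection/P06/current/UMIC/
unit	m	http://vocab.nerc.ac.uk/collection/P06/current/ULAA/
unit	degC	http://vocab.nerc.ac.uk/collection/P06/current/UPAA/
unit	Dmnless	http://vocab.nerc.ac.uk/collection/P06/current/UUUU/
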