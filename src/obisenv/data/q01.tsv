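uri	preferred_label	definition	usage_note
http://vocab.nerc.ac.uk/collection/Q01/current/Q0100002/	Sampling instrument name	The name of the gear or instrument used to collect the sample or make the in situ measurement or observation.	corresponding measurementValue should preferably point to a repository like L22; measurementUnit is left empty
http://vocab.nerc.ac.uk/collection/Q01/current/Q0100012/	Sampling device aperture diameter	The diameter of the sampling area of a device with a circular aperture (e.g. a corer or a net); the type of device is specified elsewhere.	measurementValue set to diameter value and measurementUnit set to appropriate unit from a controlled vocabulary like P06
http://vocab.nerc.ac.uk/collection/Q01/current/Q0100013/	Sampling device aperture width	The smaller dimension of the sampling area of a device with a rectangular aperture (e.g. a grab or a trawl); the type of device is specified elsewhere.	measurementValue set to width value and measurementUnit set to appropriate unit preferably from a controlled vocabulary like P06
http://vocab.nerc.ac.uk/collection/Q01/current/Q0100014/	Sampling device aperture length	The larger dimension of the sampling area of a device with a rectangular aperture (e.g. a grab); the type of device is specified elsewhere.	measurementValue set to length value and measurementUnit set to appropriate unit from a controlled vocabulary like P06
http://vocab.nerc.ac.uk/collection/Q01/current/Q0100015/	Sampling net mesh size	The mesh size of the sampling net used to obtain the sample. The type of net is specified elsewhere.	measurementValue set to mesh size value and measurementUnit set to appropriate unit from a controlled vocabulary like P06
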