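taxon	rank	clade	locality	territory	fad_ma	lad_ma	source
Hylonomus	genus	Reptilia	Joggins	West	320.8	319.6	Langsettian (Westphalian A); Joggins locality
Protoclepsydrops	genus	Synapsida	Joggins	West	320.5	319.8	Langsettian (Westphalian A); Joggins locality
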