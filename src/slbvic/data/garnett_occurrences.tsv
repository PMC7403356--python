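taxon	rank	clade	locality	territory	fad_ma	lad_ma	source
Eohaptodus	genus	Synapsida	Garnett	West	304.3	303.7	literature compilation; figure-digitised ranges
Ianthodon	genus	Synapsida	Garnett	West	304.3	303.7	literature compilation; figure-digitised ranges
Ianthasaurus	genus	Synapsida	Garnett	West	304.2	303.7	literature compilation; figure-digitised ranges
Edaphosaurus	genus	Synapsida	Garnett	West	304.2	303.7	literature compilation; figure-digitised ranges
Xyrospondylus	genus	Synapsida	Garnett	West	304.1	303.7	literature compilation; figure-digitised ranges
Clepsydrops	genus	Synapsida	Garnett	West	304.1	303.7	literature compilation; figure-digitised ranges
Ophiacodon	genus	Synapsida	Garnett	West	304.0	303.7	literature compilation; figure-digitised ranges
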