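taxon	rank	clade	locality	territory	fad_ma	lad_ma	source
Tapinocephalus	genus	Tapinocephalidae	Tapinocephalus AZ	West	265.0	260.3	literature compilation; figure-digitised ranges
Moschops	genus	Tapinocephalidae	Tapinocephalus AZ	West	264.8	260.3	literature compilation; figure-digitised ranges
Struthiocephalus	genus	Tapinocephalidae	Tapinocephalus AZ	West	264.6	260.3	literature compilation; figure-digitised ranges
Struthiocephalellus	genus	Tapinocephalidae	Tapinocephalus AZ	West	264.5	260.3	literature compilation; figure-digitised ranges
Struthionops	genus	Tapinocephalidae	Tapinocephalus AZ	West	264.4	260.3	literature compilation; figure-digitised ranges
Keratocephalus	genus	Tapinocephalidae	Tapinocephalus AZ	West	264.2	260.3	literature compilation; figure-digitised ranges
Mormosaurus	genus	Tapinocephalidae	Tapinocephalus AZ	West	264.0	260.3	literature compilation; figure-digitised ranges
Phocosaurus	genus	Tapinocephalidae	Tapinocephalus AZ	West	263.8	260.3	literature compilation; figure-digitised ranges
Riebeeckosaurus	genus	Tapinocephalidae	Tapinocephalus AZ	West	263.6	260.3	literature compilation; figure-digitised ranges
Criocephalosaurus	genus	Tapinocephalidae	Tapinocephalus AZ	West	263.4	260.3	literature compilation; figure-digitised ranges
Mastersonia	genus	Tapinocephalidae	Tapinocephalus AZ	West	263.2	260.3	literature compilation; figure-digitised ranges
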