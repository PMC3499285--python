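gene	position	major	minor	amino_acids	rflp	maf
pBD1	171	A	G	.	BstNI	0.177
pBD4	65	G	A	R/K	EcoRV	0.451
pBD113	114	A	G	.	.	0.029
pBD114	186	G	A	.	.	0.09
pBD115	144	A	T	Q/H	.	0.057
pBD115	291	G	A	.	.	0.043
pBD121	96	G	A	.	PciI	0.2
pBD133	196	A	C	K/Q	.	0.043
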