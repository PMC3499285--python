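gene	accession	nt_position	forward	reverse	annealing_c	product_bp
pBD105	FP102601.2	20573-25396	CTCAATTTACATCAGGGTGC	ACAACCTTCTCGTCCTCAGT	60	135
pBD112	CU041392.3	49146-58607	TGTGTAGACGGAAGCTTGAG	GTCACATTCTCTCATGCAGC	60	244
pBD4	CU041392.3	63852-70272	GTGGCTTGGATTTGAGGAGAGAGT	AGTGATACACAGGCCTGGAAGGAT	58	232
pBD114	CU041392.3	94921-105728	ACCTTGGTGGATCCTGAACGATGC	TCAAACGCCCTCTGAATGCAGCA	64	128
pBD133	CU041392.3	111793-117208	GTGCCATGAAAGACACCTAT	CAGACTTCTCCATGCAACAG	60	125
pBD108	CU442750.3	1195-6843	GACGATTGTCATTCTTCTGATCCTGG	TAGGTTGACTTGTGGTGCCCGAAA	58	258
pBD116	CU442750.3	21853-26511	CTGATCCTGGTTCATAAGAC	GAATCCTCCTTCTCGTTAG	60	211
pBD118	CU442750.3	75980-87519	CTGTTCCTACCACAAGTGAT	GTGCGAGAAGTGACAGTATT	60	184
pBD119	CU442750.3	89342-101888	CTGTTTCTTGCCATCCTT	TACATAGGACTGGAGGCAGC	56	168
pBD122	CU442750.3	125631-133938	GCTGCACTATTGCTCTTGTC	TCACACAGCACAGTTTACCA	62	158
pBD123	CU442750.3	143565-150992	TGGAATCTTCACGGCAAAT	TGATACTTGGGCTTCACACA	68	100
pBD124	CU442750.3	158778-164429	CTTCTGCTTATTGTGGCTCT	ATCTTGGCCATCTTGAGTC	56	187
pBD115	CU627978.3	88572-92708	CTTAGCTGTCCTTGTGGTCC	CAAGCCTTAGCTGTACTTGC	64	227
pBD128	CU627978.3	18063-21789	GGTTCTCATTATCCTGCTGT	TGTGTTCACTGTGACAGTGG	60	258
pBD129	CU606854.2	119234-124263	CAAAGACCACTGTGCCGTGAATGA	TTGATGCTGGCGAAAGGGTTGGTA	58	239
pBD3	.	.	CTTCCTATCCAGTCTCAGTGTTCTGC	GGCTTCTGTAGACTTCAAGGAGACAT	58	308
pBD104	.	.	TCCTTCCACGTATGGAGGCTTGTT	TTACAATACCTCCGGCAGCGAGAA	58	332
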