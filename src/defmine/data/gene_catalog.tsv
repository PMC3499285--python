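gene	status	accession	chromosome
pBD1	reported	.	SSC15
pBD2	reported	.	SSC15
pBD3	reported	.	unplaced
pBD4	reported	CU041392.3	SSC7
pBD104	reported	.	SSC15
pBD105	new	FP102601.2	SSC15
pBD106	new	.	SSC15
pBD108	reported	CU442750.3	.
pBD112	new	CU041392.3	SSC7
pBD113	new	.	SSC7
pBD114	reported	CU041392.3	SSC7
pBD115	new	CU627978.3	SSC17
pBD116	new	CU442750.3	SSC17
pBD117	partial_psi	.	SSC17
pBD118	new	CU442750.3	SSC17
pBD119	new	CU442750.3	SSC17
pBD121	reported	.	SSC17
pBD122	new	CU442750.3	SSC17
pBD123	new	CU442750.3	SSC17
pBD124	new	CU442750.3	SSC17
pBD125	reported	.	.
pBD127	partial_psi	.	SSC17
pBD128	new	CU627978.3	SSC17
pBD129	reported	CU606854.2	SSC17
pBD130	new	.	SSC15
pBD131	new	.	SSC14
pBD133	new	CU041392.3	SSC7
pBD134	new	.	SSC14
pBD135	new	.	SSC14
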