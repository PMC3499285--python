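# Anchor coordinates (synthetic bp, flanking the printed clusters).
species	chromosome	name	start	end
pig	SSC7	PGK2	900000	905000
pig	SSC7	TFAP2D	1220000	1225000
pig	SSC15	AGPAT5	900000	905000
pig	SSC15	SPATA4	1250000	1255000
pig	SSC17	ZCCHC3	880000	885000
pig	SSC17	TRIB3	900000	905000
pig	SSC17	BCL2L1	1430000	1435000
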