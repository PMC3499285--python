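# Historically named pig defensins: retained names and the human ortholog
# number used for cross-species matching (renaming them would collide with
# an established literature, so the names stay and the evidence is recorded).
species	gene	retained_name	ortholog_number	nearest_human
pig	pBD1	pBD1	4	DEFB4
pig	pBD2	pBD2	1	DEFB1
pig	pBD3	pBD3	103	DEFB103
pig	pBD4	pBD4	110	DEFB110
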