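# Flanking anchor pairs per cluster chromosome. The SSC17 upstream anchor
# is given differently in two places of the source record (ZCCHC3 aka
# LOC100519451, and TRIB3); both candidates are stored, neither resolved.
# The SSC14 cluster has no conserved external anchors; its boundary
# defensins serve as markers.
species	chromosome	upstream	downstream
pig	SSC7	PGK2	TFAP2D
pig	SSC14	pBD135	pBD131
pig	SSC15	AGPAT5	SPATA4
pig	SSC17	ZCCHC3|TRIB3	BCL2L1
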