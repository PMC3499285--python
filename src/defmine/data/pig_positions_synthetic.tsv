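# Synthetic coordinates: chromosome assignments and gene order follow the
# published comparative map; bp positions are evenly spaced stand-ins
# (genome-build coordinates are not part of the printed record).
gene	species	chromosome	start	end	strand	pseudo	inferred_position
pBD133	pig	SSC7	1000000	1002000	+	no	.
pBD114	pig	SSC7	1030000	1032000	+	no	.
pBD113	pig	SSC7	1060000	1062000	+	no	.
pBD4	pig	SSC7	1090000	1092000	+	no	.
pBD112	pig	SSC7	1120000	1122000	+	no	.
pBD135	pig	SSC14	1000000	1002000	+	no	.
pBD134	pig	SSC14	1030000	1032000	+	no	.
pBD131	pig	SSC14	1060000	1062000	+	no	.
pBD105	pig	SSC15	1000000	1002000	+	no	.
pBD106	pig	SSC15	1030000	1032000	+	no	.
pBD104	pig	SSC15	1060000	1062000	+	no	.
pBD1	pig	SSC15	1090000	1092000	+	no	.
pBD2	pig	SSC15	1120000	1122000	+	no	.
pBD130	pig	SSC15	1150000	1152000	+	no	.
pBD129	pig	SSC17	1000000	1002000	+	no	.
pBD128	pig	SSC17	1030000	1032000	+	no	.
pBD127	pig	SSC17	1060000	1062000	+	yes	.
pBD115	pig	SSC17	1090000	1092000	+	no	.
pBD124	pig	SSC17	1120000	1122000	+	no	.
pBD123	pig	SSC17	1150000	1152000	+	no	.
pBD122	pig	SSC17	1180000	1182000	+	no	.
pBD121	pig	SSC17	1210000	1212000	+	no	.
pBD119	pig	SSC17	1240000	1242000	+	no	.
pBD118	pig	SSC17	1270000	1272000	+	no	.
pBD117	pig	SSC17	1300000	1302000	+	yes	.
pBD116	pig	SSC17	1330000	1332000	+	no	.
pBD3	pig	unplaced	1	2000	+	no	SSC15
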