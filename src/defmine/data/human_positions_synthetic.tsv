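# Synthetic coordinates: chromosome assignments and gene order follow the
# published comparative map; bp positions are evenly spaced stand-ins.
gene	species	chromosome	start	end	strand	pseudo	inferred_position
DEFB133	human	HSA6	1000000	1002000	+	no	.
DEFB114	human	HSA6	1030000	1032000	+	no	.
DEFB113	human	HSA6	1060000	1062000	+	no	.
DEFB110	human	HSA6	1090000	1092000	+	no	.
DEFB112	human	HSA6	1120000	1122000	+	no	.
DEFB105	human	HSA8	1000000	1002000	+	no	.
DEFB106	human	HSA8	1030000	1032000	+	no	.
DEFB104	human	HSA8	1060000	1062000	+	no	.
DEFB4	human	HSA8	1090000	1092000	+	no	.
DEFB1	human	HSA8	1120000	1122000	+	no	.
DEFB130	human	HSA8	1150000	1152000	+	no	.
DEFB135	human	HSA8	1180000	1182000	+	no	.
DEFB134	human	HSA8	1210000	1212000	+	no	.
DEFB131	human	HSA8	1240000	1242000	+	no	.
DEFB129	human	HSA20	1000000	1002000	+	no	.
DEFB128	human	HSA20	1030000	1032000	+	no	.
DEFB127	human	HSA20	1060000	1062000	+	no	.
DEFB115	human	HSA20	7000000	7002000	+	no	.
DEFB124	human	HSA20	7030000	7032000	+	no	.
DEFB123	human	HSA20	7060000	7062000	+	no	.
DEFB122	human	HSA20	7090000	7092000	+	no	.
DEFB121	human	HSA20	7120000	7122000	+	no	.
DEFB119	human	HSA20	7150000	7152000	+	no	.
DEFB118	human	HSA20	7180000	7182000	+	no	.
DEFB117	human	HSA20	7210000	7212000	+	no	.
DEFB116	human	HSA20	7240000	7242000	+	no	.
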