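enzyme	site
AluI	AGCT
ApoI	RAATTY
AvaII	GGWCC
BamHI	GGATCC
BfaI	CTAG
BstNI	CCWGG
Cac8I	GCNNGC
DdeI	CTNAG
DraI	TTTAAA
EcoRI	GAATTC
EcoRV	GATATC
HaeIII	GGCC
HhaI	GCGC
HindIII	AAGCTT
HinfI	GANTC
HpaII	CCGG
KpnI	GGTACC
MboI	GATC
MseI	TTAA
NcoI	CCATGG
NdeI	CATATG
NlaIII	CATG
PciI	ACATGT
PstI	CTGCAG
RsaI	GTAC
SacI	GAGCTC
SalI	GTCGAC
ScrFI	CCNGG
SmaI	CCCGGG
SphI	GCATGC
StyI	CCWWGG
TaqI	TCGA
Tsp509I	AATT
XbaI	TCTAGA
XhoI	CTCGAG
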