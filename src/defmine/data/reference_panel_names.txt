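# The 57-entry reference panel name list, stored verbatim from the source
# record. Note: DEFB132 appears twice in the human series (56 unique
# symbols); the duplication is preserved, not resolved.
DEFB110
DEFB112
DEFB113
DEFB114
DEFB133
DEFB1
DEFB4
DEFB103
DEFB104
DEFB105
DEFB106
DEFB107
DEFB130
DEFB131
DEFB132
DEFB134
DEFB135
DEFB136
DEFB137
DEFB115
DEFB116
DEFB118
DEFB119
DEFB121
DEFB123
DEFB124
DEFB125
DEFB126
DEFB127
DEFB128
DEFB129
DEFB132
BBD4
BBD5
BBD7
BBD10
BBD103A
BBD103B
BBD119
BBD122
BBD122A
BBD123
BBD124
BBD300
EBD
TAP
LAP
pBD1
pBD2
pBD3
pBD4
pBD104
pBD108
pBD114
pBD123
pBD125
pBD129
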