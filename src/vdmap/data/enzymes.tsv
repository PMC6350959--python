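# name	recognition	cut_offset
DdeI	CTNAG	1
EcoRI	GAATTC	1
HindIII	AAGCTT	1
TaqI	TCGA	1
MseI	TTAA	1
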