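gene	role	forward	reverse
RAF1	target	CTGGCTCCCTCAGGTTTAAGAA	AAGCTCCCTGTATGTGCTCC
FLT3	target	CTCAAGGAAACGGCCATCCT	AACACGGCCATCCACATTCT
FLT1	target	TGTCGTGTAAGGAGTGGACC	GCACCTGCTGTTTTCGATGT
FGFR1	target	GAGTGACTTCCACAGCCAGA	GGATGCACTGGAGTCAGCAG
BRAF	target	CAGAGGACAGTGGTACCTGC	CAGCACAGCACTCTGGGATT
PDGFRB	target	GCAAAACCACCATTGGGGAC	TGCGTTCACAGAGACGTTGA
KDR	target	GAAACTGACTTGGCCTCGGT	CACGACTCCATGTTGGTCACT
KIT	target	GCACAATGGCACGGTTGAAT	GGTGTGGGGATGGATTTGCT
ACTB	housekeeping	ACAGAGCCTCGCCTTTGC	CGCGGCGATATCATCATCCA
VCP	housekeeping	TGGAAGCGTATCGACCCATC	CTTTGAACTCCACAGCACGC
DIABLO	housekeeping	AATGGCGGCTCTGAAGAGTT	AAACTCGAGCCAAGCAGGAA
EIF3B	housekeeping	GGCGAACACCATCTTCTGGA	TGTCCACAAACGCTAAGGCA
PSMB2	housekeeping	GCAGCAGCTAACTTCACACG	AGCCAGGAGGAGGTTCACAT
POLR2C	housekeeping	TCTTCATCGCTGAGGTTCCC	ATCCAAGCCTGTGAGCAATGA
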