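gene	p_value	log2_fold_change
RAF1	0.56	0.072
BRAF	0.37	0.071
RET	0.54	-0.037
FLT1	0.0032	1.155
FGFR1	0.1	0.149
KIT	0.72	0.029
PDGFRB	0.013	0.273
FLT3	0.67	0.011
FLT4	0.54	-0.010
KDR	0.2	0.119
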