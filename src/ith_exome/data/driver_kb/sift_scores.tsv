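# synthetic stand-in SIFT scores (< 0.05 = predicted deleterious)
gene	aa_change	score
CSMD1	Val2977Met	0.01
SMAD4	Ser72Thr	0.02
FAT2	Arg2024Thr	0.30
MSN	Val268Ile	0.61
MYT1L	Ser696Asn	0.44
DNAH11	Glu1074Lys	0.21
MUC16	Arg2736Trp	0.34
MUC16	Thr2087Met	0.18
MSH6	Arg33Cys	0.12
DNAH9	Phe4464Ser	0.27
PTPRC	Gln407Lys	0.52
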