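patient	clonality	gene	consequence	aa_change
Pat1	common	CSMD1	missense	Val2977Met
Pat1	common	KRAS	missense	Gly12Asp
Pat1	common	SMAD4	missense	Ser72Thr
Pat1	common	FAT2	missense	Arg2024Thr
Pat1	common	MSN	missense	Val268Ile
Pat1	common	MYT1L	missense	Ser696Asn
Pat1	common	SRC	frameshift	Thr524HisfsTer52
Pat2	common	EPHA2	missense	Arg861Cys
Pat2	common	IDH2	missense	Arg172Trp
Pat2	common	DNAH11	missense	Glu1074Lys
Pat2	common	MUC16	missense	Arg2736Trp
Pat3	common	IDH1	missense	Arg132Cys
Pat3	common	MUC16	missense	Thr2087Met
Pat3	common	BAP1	splice_site	NA
Pat3	common	EPHA2	nonsense	Cys262Ter
Pat4	private_peripheral	MSH6	missense	Arg33Cys
Pat4	common	BAP1	frameshift	Asn133GlnfsTer10
Pat4	common	DNAH9	missense	Phe4464Ser
Pat4	common	GNA14	splice_site	NA
Pat4	common	PTPRC	missense	Gln407Lys
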