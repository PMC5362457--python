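# synthetic stand-in for a known-mutation extract: exact matches and
# residue-proximity anchors
gene	aa_change
KRAS	Gly12Asp
EPHA2	Arg861Cys
IDH2	Arg172Trp
IDH1	Arg132Cys
DNAH11	Ala1071Thr
MUC16	Ser2733Phe
MUC16	Pro2089Leu
MSH6	Pro29Ser
BAP1	Gln130Ter
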