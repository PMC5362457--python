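gene	source
CSMD1	recurrent_iCCA_study
KRAS	recurrent_iCCA_study
KRAS	cosmic_ge3pct_biliary
KRAS	cancer_gene_census
SMAD4	cosmic_ge3pct_biliary
SMAD4	cancer_gene_census
FAT2	recurrent_iCCA_study
MSN	cancer_gene_census
MYT1L	recurrent_iCCA_study
EPHA2	recurrent_iCCA_study
IDH2	cosmic_ge3pct_biliary
IDH2	cancer_gene_census
DNAH11	recurrent_iCCA_study
MUC16	recurrent_iCCA_study
IDH1	cosmic_ge3pct_biliary
IDH1	cancer_gene_census
BAP1	recurrent_iCCA_study
BAP1	cancer_gene_census
MSH6	cancer_gene_census
DNAH9	recurrent_iCCA_study
GNA14	recurrent_iCCA_study
PTPRC	cancer_gene_census
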