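# Clinicopathological characteristics of the four-patient iCCA cohort
# (TNM / UICC 7th edition staging; Diameter = tumor diameter in cm,
# Distance = distance between central and peripheral sample in cm)
case	age	sex	diameter_cm	distance_cm	T	N	M	L	V	pN	G	R	UICC
Pat1	69	F	8.5	4	1	x	0	0	0	0	2	1	IVA
Pat2	67	F	10	5	2b	1	0	0	0	1	2	1	IVA
Pat3	86	F	4.7	1.7	3	x	0	0	0	0	3	0	IVA
Pat4	60	M	5	1.7	1	0	0	0	0	0	2	0	I
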