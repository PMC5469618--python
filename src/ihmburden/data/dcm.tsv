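# transcription of the published cohort variant tables;
# regions/md/mesa columns carry the printed structural annotations
# (region cell names match the packaged region fixture)
gene	substitution	pclass	cohort	multiplicity	regions	md	mesa	dq
MYH7	G144V	LPV	DCM	1			1	0
MYH7	G178R	LPV	DCM	1		nucleotide	0	+2
MYH7	G181R	LPV	DCM	1		nucleotide	0	+2
MYH7	I201T	LPV	DCM	1			1	0
MYH7	R243H	LPV	DCM	1		nucleotide	0	-1
MYH7	G245E	LPV	DCM	1		nucleotide	0	-1
MYH7	I248F	LPV	DCM	1			0	0
MYH7	R369Q	LPV	DCM	1	d2-free		0	-2
MYH7	D469Y	LPV	DCM	1		nucleotide	0	+1
MYH7	I524V	LPV	DCM	1	f2-head		0	0
MYH7	E525K	LPV	DCM	1	f2-head		1	+2
MYH7	I533V	LPV	DCM	1	f2-head	actin	0	0
MYH7	R567H	LPV	DCM	1		actin	0	-1
MYH7	N597K	LPV	DCM	1			0	+1
MYH7	C672F	LPV	DCM	1			0	0
MYH7	R783P	LPV	DCM	1	scELC-neck-blocked;scELC-neck-free		0	-2
MYH7	R904C	PV	DCM	1	f2-tail		0	-2
MYH7	R904H	LPV	DCM	1	f2-tail		0	-1
MYH7	E1152V	LPV	DCM	1			0	+1
MYH7	R1193H	LPV	DCM	1	lmm		0	-1
MYH7	E1286K	LPV	DCM	1	lmm		0	+2
MYH7	R1434C	LPV	DCM	1	lmm		0	-2
MYH7	D1450N	LPV	DCM	1	lmm		0	+1
MYH7	R1574W	LPV	DCM	1	lmm		0	-2
MYH7	Q1794E	LPV	DCM	1	lmm		0	-1
MYH7	E1801K	LPV	DCM	1	lmm		0	+2
MYH7	E1914K	LPV	DCM	1	lmm		0	+2
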