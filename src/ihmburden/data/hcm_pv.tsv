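# transcription of the published cohort variant tables;
# regions/md/mesa columns carry the printed structural annotations
# (region cell names match the packaged region fixture)
gene	substitution	pclass	cohort	multiplicity	regions	md	mesa	dq
MYH7	Y115H	PV	HCM	1			0	+1
MYH7	E170K	PV	HCM	1	d1-blocked		1	+2
MYH7	R249Q	PV	HCM	1			1	-2
MYH7	I263T	PV	HCM	1			0	0
MYH7	P307H	PV	HCM	1			0	+1
MYH7	R403W	PV	HCM	1	d1-blocked	actin	1	-2
MYH7	R403G	PV	HCM	1	d1-blocked	actin	1	-2
MYH7	R403L	PV	HCM	1	d1-blocked	actin	1	-2
MYH7	R403Q	PV	HCM	1	d1-blocked	actin	1	-2
MYH7	R442C	PV	HCM	1	d1-blocked		1	-2
MYH7	R453C	PV	HCM	1	g-head;d1-free		1	-2
MYH7	E483K	PV	HCM	2	j-blocked;d2-free		0	+2
MYH7	M515T	PV	HCM	1	j-blocked;d2-free	relay	1	0
MYH7	V606M	PV	HCM	1	e-blocked	actin	1	0
MYH7	R663H	PV	HCM	1	f2-head		1	-1
MYH7	M690T	PV	HCM	1			0	0
MYH7	I702N	PV	HCM	1			0	0
MYH7	G708A	PV	HCM	1			1	0
MYH7	G716R	PV	HCM	1	i-blocked;d2-free;scELC-conv-blocked	converter	1	+2
MYH7	R719W	PV	HCM	1	i-blocked;d2-free;scELC-conv-blocked	converter	1	-2
MYH7	R719Q	PV	HCM	1	i-blocked;d2-free;scELC-conv-blocked	converter	1	-2
MYH7	R723G	PV	HCM	1	i-blocked;d2-free;scELC-conv-blocked	converter	0	-2
MYH7	R723C	PV	HCM	1	i-blocked;d2-free;scELC-conv-blocked	converter	0	-2
MYH7	I736T	PV	HCM	1	j-blocked;d2-free;scELC-conv-blocked	converter	1	0
MYH7	G741W	PV	HCM	1	j-blocked;d2-free;scELC-conv-blocked	converter	0	0
MYH7	G741R	PV	HCM	1	j-blocked;d2-free;scELC-conv-blocked	converter	0	+2
MYH7	K762R	PV	HCM	1	j-blocked;d2-free;scELC-conv-blocked	converter	1	+1
MYH7	K766Q	PV	HCM	1	d2-free	converter	1	-1
MYH7	A797T	PV	HCM	1	scELC-neck-blocked;scELC-neck-free		0	0
MYH7	F834L	PV	HCM	1	scRLC-blocked;scRLC-free		0	0
MYH7	S842N	PV	HCM	1	scRLC-blocked;scRLC-free		0	0
MYH7	R870H	PV	HCM	1	g-tail		0	-1
MYH7	D906G	PV	HCM	1	f2-tail		0	+1
MYH7	L908V	PV	HCM	1	f2-tail		0	0
MYH7	L915P	PV	HCM	1	a-tail		0	0
MYH7	E924K	PV	HCM	1	a-tail		0	+2
MYH7	E930K	PV	HCM	1	a-tail		0	+2
MYH7	A1379T	PV	HCM	1	lmm		0	0
MYH7	R1781C	PV	HCM	1	lmm		0	-2
MYL3	M149V	PV	HCM	1	elc-anchoring-i;elc-stab-e;elc-scaff-blocked		0	0
MYL3	H155D	PV	HCM	1	elc-anchoring-i;elc-scaff-blocked;elc-scaff-free;elc-stab-e		0	-2
MYL2	E22K	PV	HCM	1	rlc-regulating;rlc-scaff		0	+2
MYL2	R58Q	PV	HCM	1	rlc-regulating;rlc-scaff		0	-2
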