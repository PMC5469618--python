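# transcription of the published cohort variant tables;
# regions/md/mesa columns carry the printed structural annotations
# (region cell names match the packaged region fixture)
gene	substitution	pclass	cohort	multiplicity	regions	md	mesa	dq
MYH7	R17C	LPV	HCM	1	h-blocked		1	-2
MYH7	R143Q	LPV	HCM	1			1	-2
MYH7	K146N	LPV	HCM	1			1	-1
MYH7	R169G	LPV	HCM	1	d1-blocked		1	-2
MYH7	R169K	LPV	HCM	1	d1-blocked		1	-1
MYH7	R169S	LPV	HCM	1	d1-blocked		1	-2
MYH7	Q193R	LPV	HCM	1			1	+2
MYH7	A199V	LPV	HCM	1			1	0
MYH7	R204C	LPV	HCM	1		actin	1	-2
MYH7	G214D	LPV	HCM	1		actin	1	-1
MYH7	N232H	LPV	HCM	1			0	+1
MYH7	D239N	LPV	HCM	1		nucleotide	0	+1
MYH7	R243H	LPV	HCM	1		nucleotide	0	-1
MYH7	F244C	LPV	HCM	1		nucleotide	0	0
MYH7	K246I	LPV	HCM	1			0	-1
MYH7	F247L	LPV	HCM	1			0	0
MYH7	I248T	LPV	HCM	1			0	0
MYH7	G256E	LPV	HCM	1			1	-1
MYH7	I263M	LPV	HCM	1			0	0
MYH7	L267V	LPV	HCM	1			0	0
MYH7	Y283C	LPV	HCM	1			0	0
MYH7	S291F	LPV	HCM	1			0	0
MYH7	D309N	LPV	HCM	1			0	+1
MYH7	I323N	LPV	HCM	1			0	0
MYH7	E328G	LPV	HCM	1			0	+1
MYH7	V338M	LPV	HCM	1			1	0
MYH7	K351E	LPV	HCM	1			0	-2
MYH7	G354S	LPV	HCM	1			0	0
MYH7	E374V	LPV	HCM	1	d2-free	actin	0	+1
MYH7	A381D	LPV	HCM	1	d2-free	actin	0	-1
MYH7	Y386C	LPV	HCM	1	e-blocked		0	0
MYH7	V406M	LPV	HCM	1	d1-free	actin	1	0
MYH7	Y410D	LPV	HCM	1	d1-free	actin	0	-1
MYH7	V411I	LPV	HCM	1	d1-free	actin	0	0
MYH7	L427M	LPV	HCM	1			0	0
MYH7	T449S	LPV	HCM	1	g-head;d1-free		1	0
MYH7	R453S	LPV	HCM	1	g-head;d1-free		1	-2
MYH7	R453H	LPV	HCM	1	g-head;d1-free		1	-1
MYH7	I457T	LPV	HCM	1			0	0
MYH7	I478N	LPV	HCM	1			0	0
MYH7	N479S	LPV	HCM	1			0	0
MYH7	M493V	LPV	HCM	1	j-blocked;d2-free	relay	0	0
MYH7	M493L	LPV	HCM	1	j-blocked;d2-free	relay	0	0
MYH7	M493I	LPV	HCM	1	j-blocked;d2-free	relay	0	0
MYH7	E497G	LPV	HCM	1	j-blocked;d2-free	relay	1	+1
MYH7	E497D	LPV	HCM	1	j-blocked;d2-free	relay	1	0
MYH7	I521T	LPV	HCM	1			0	0
MYH7	E536D	LPV	HCM	1	f2-head	actin	1	0
MYH7	H576R	LPV	HCM	1		actin	0	+1
MYH7	G584R	LPV	HCM	1			1	+2
MYH7	V586A	LPV	HCM	1			0	0
MYH7	R652G	LPV	HCM	1	f2-head		1	-2
MYH7	K657Q	LPV	HCM	1	f2-head		1	-1
MYH7	R663C	LPV	HCM	1	f2-head		1	-2
MYH7	R671C	LPV	HCM	1			0	-2
MYH7	R694C	LPV	HCM	1			1	-2
MYH7	R694H	LPV	HCM	1			1	-1
MYH7	P710H	LPV	HCM	1		converter	1	+1
MYH7	P710L	LPV	HCM	1		converter	1	0
MYH7	P731A	LPV	HCM	1	j-blocked;scELC-conv-blocked		1	0
MYH7	G733E	LPV	HCM	1	j-blocked;d2-free;scELC-conv-blocked	converter	1	-1
MYH7	R739S	LPV	HCM	1	j-blocked;d2-free;scELC-conv-blocked	converter	1	-2
MYH7	K740N	LPV	HCM	1	j-blocked;d2-free;scELC-conv-blocked		1	-1
MYH7	L749Q	LPV	HCM	1	j-blocked;scELC-conv-blocked		0	0
MYH7	F758C	LPV	HCM	1	j-blocked;scELC-conv-blocked		1	0
MYH7	V763M	LPV	HCM	1	d2-free;scELC-conv-free	converter	0	0
MYH7	G768R	LPV	HCM	1		converter	1	+2
MYH7	L781P	LPV	HCM	1	scELC-neck-blocked;scELC-neck-free		1	0
MYH7	R783H	LPV	HCM	1	scELC-neck-blocked;scELC-neck-free		0	-1
MYH7	R787C	LPV	HCM	1	scELC-neck-blocked;scELC-neck-free		0	-2
MYH7	A797P	LPV	HCM	1	scELC-neck-blocked;scELC-neck-free		0	0
MYH7	L811P	LPV	HCM	1	scELC-neck-blocked;scELC-neck-free;scRLC-blocked;scRLC-free		0	0
MYH7	K847E	LPV	HCM	1			0	-2
MYH7	E848G	LPV	HCM	1			0	+1
MYH7	M849T	LPV	HCM	1			0	0
MYH7	A850D	LPV	HCM	1			0	-1
MYH7	R858H	LPV	HCM	1	g-tail		0	-1
MYH7	E894G	LPV	HCM	1	f1-tail;f2-tail		0	+1
MYH7	L898V	LPV	HCM	1	f1-tail;f2-tail		0	0
MYH7	A901P	LPV	HCM	1	f1-tail;f2-tail		0	0
MYH7	E903G	LPV	HCM	1	f1-tail;f2-tail		0	+1
MYH7	Q914H	LPV	HCM	1			0	+1
MYH7	D928N	LPV	HCM	1	a-tail		0	+1
MYH7	E929K	LPV	HCM	1	a-tail		0	+2
MYH7	E930Q	LPV	HCM	1	a-tail		0	+1
MYH7	E949K	LPV	HCM	1			0	+2
MYH7	E967K	LPV	HCM	1			0	+2
MYH7	R1053Q	LPV	HCM	1			0	-2
MYH7	E1356K	LPV	HCM	1	lmm		0	+2
MYH7	R1382Q	LPV	HCM	1	lmm		0	-2
MYH7	L1428S	LPV	HCM	1	lmm		0	0
MYH7	R1606C	LPV	HCM	1	lmm		0	-2
MYH7	A1763T	LPV	HCM	1	lmm		0	0
MYH7	R1781H	LPV	HCM	1	lmm		0	-1
MYH7	M1782V	LPV	HCM	1	lmm		0	0
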