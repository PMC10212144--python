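domain_type	subtype_scope	motif_id	start	end	consensus	prevalent_length	optional
C	all	C1	21	30	SxAQxR(L/M)(W/Y)xL	10	0
C	all	C2	61	69	RHExLRTxF	9	0
C	all	C3	110	119	MHHxISDG(W/V)S	10	0
C	all	C4	170	176	YxD(F/Y)AVW	7	0
C	all	C5	242	252	(I/V)GxFVNT(Q/L)(C/A)xR	11	0
C	all	C6	298	304	(H/N)QD(Y/V)PFE	7	0
C	all	C7	365	372	RDxSRNPL	8	0
A	all	Aa1	6	11	PxxxAV	6	1
A	all	A1	21	26	L(T/S)YxEL	6	0
A	all	A2	55	66	LKAGxAYL(V/L)P(L/I)D	12	0
A	all	A3	137	152	LAYxxYTSG(S/T)TGxPKG	16	0
A	all	A4	178	181	FDxS	4	0
A	all	A5	258	264	NxYGPTE	7	0
A	all	G	282	288	(I/V)P(I/L)G(K/R)P(I/L)	7	1
A	all	A6	308	322	GELxIxGxG(V/L)(A/E)RGYL	15	0
A	all	A7	351	356	Y(R/K)TGDL	6	0
A	all	A8	377	396	GRxDxQVKIRGxRIELGEIE	20	0
A	all	A9	432	438	LPxYM(I/V)P	7	0
A	all	A10	457	462	NGK(V/L)DR	6	0
T	all	Ta1	6	16	ExxxxxxxxxL	11	1
T	all	T1	24	29	(L/F)GG(D/H)S(I/L)	6	0
E	all	E1	13	18	PIQxWF	6	0
E	all	E2	44	52	HHxISDG(W/V)S	9	0
E	all	E3	83	90	DxLLxAxG	8	0
E	all	E4	131	136	EGHGRE	6	0
E	all	E5	172	183	RTVGWFTxxYP(V/L)	12	0
E	all	E6	224	231	PxxGxGYG	8	0
E	all	E7	257	262	FNYLG(Q/R)	6	0
TE	all	TE1	56	60	G(W/Y)SAG	5	0
ACP	all	ACP1	36	41	xGxDSL	6	0
C	Cyc	C3	110	119	DxxxxDGxSx	10	0
C	LCL-A	C3	110	119	SHxxxDxx(T/S)x	10	0
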