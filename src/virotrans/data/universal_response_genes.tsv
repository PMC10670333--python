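timepoint_h	direction	gene_id
12	up	H2BC5
12	up	H4C5
12	up	H2BC8
12	up	H4C8
12	up	H4C2
12	down	MARCKS
24	up	AHSA2P
24	up	AOC2
24	up	ARID4B
24	up	AVIL
24	up	AXIN2
24	up	B3GNT2
24	up	BAZ2A
24	up	BRD1
24	up	CCDC17
24	up	CCNL1
24	up	CDKN2AIP
24	up	CLCN6
24	up	CLDN15
24	up	CLK4
24	up	CMYA5
24	up	CWC22
24	up	CWC25
24	up	DNAJA1
24	up	DNHD1
24	up	FGFR1OP2
24	up	FLCN
24	up	FNBP4
24	up	H1-2
24	up	H1-3
24	up	H1-4
24	up	H2AC17
24	up	H2AC4
24	up	H2AC6
24	up	H2AC8
24	up	H2BC11
24	up	H2BC15
24	up	H2BC18
24	up	H2BC21
24	up	H2BC4
24	up	H2BC5
24	up	H2BC8
24	up	H2BC9
24	up	H3C3
24	up	H3C4
24	up	H4C2
24	up	H4C3
24	up	H4C5
24	up	H4C8
24	up	HSPA1B
24	up	HSPA6
24	up	JMJD1C
24	up	KDM6A
24	up	KHDC4
24	up	LIME1
24	up	LOC102724814
24	up	LOC284454
24	up	LOC729603
24	up	LSMEM1
24	up	LTB4R
24	up	MAPK8IP3
24	up	MBIP
24	up	MORC3
24	up	NFKBIZ
24	up	NXF1
24	up	PAXBP1
24	up	PPTC7
24	up	PTGS2
24	up	PUM2
24	up	QRICH2
24	up	RBBP6
24	up	RBM33
24	up	RBM5
24	up	RNU4-2
24	up	RPPH1
24	up	RSRC2
24	up	SCARNA2
24	up	SERTAD1
24	up	SLC25A25
24	up	SLC8A2
24	up	SMPD4BP
24	up	SYNGAP1
24	up	TENT4B
24	up	TMEM259
24	up	UBE2B
24	up	WAC
24	up	YOD1
24	up	ZFYVE27
24	up	ZNF160
24	up	ZNF211
24	up	ZNF451
24	down	ACTB
24	down	ACTR1A
24	down	AP2B1
24	down	ARF3
24	down	ARPC4
24	down	ATP5MC2
24	down	C11orf68
24	down	CALD1
24	down	CAPNS1
24	down	CAPRIN1
24	down	CAPZB
24	down	CAVIN1
24	down	CDC42
24	down	CDK4
24	down	CFL2
24	down	CLTA
24	down	CNN2
24	down	COPZ1
24	down	CSRP1
24	down	DAZAP2
24	down	EHD2
24	down	EI24
24	down	EPN1
24	down	FAM98A
24	down	FSCN1
24	down	IMMT
24	down	LASP1
24	down	LOXL1
24	down	LRRC59
24	down	MAP1A
24	down	MAP4
24	down	MARCKS
24	down	NONO
24	down	PABPC4
24	down	PARVA
24	down	PLIN3
24	down	RHOA
24	down	RNF20
24	down	RSU1
24	down	RTL8C
24	down	S100A11
24	down	SH3BGRL3
24	down	SKI
24	down	SMARCC1
24	down	SNX12
24	down	STMP1
24	down	TLN1
24	down	TRAPPC1
24	down	TXN2
24	down	UQCR10
24	down	UROS
24	down	USP22
24	down	VIM
24	down	WFS1
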