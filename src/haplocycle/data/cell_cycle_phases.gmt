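G1S	Whitfield-derived G1/S phase signature	MCM5	PCNA	TYMS	FEN1	MCM2	MCM4	RRM1	UNG	GINS2	MCM6	CDCA7	DTL	PRIM1	UHRF1	HELLS	RFC2	RPA2	NASP	RAD51AP1	GMNN	WDR76	SLBP	CCNE1	CCNE2	UBR7	POLD3	MSH2	ATAD2	CDC6	E2F1
S	Whitfield-derived S phase signature	RRM2	RAD51	CDC45	EXO1	TIPIN	DSCC1	BLM	CASP8AP2	USP1	CLSPN	POLA1	CHAF1B	BRIP1	E2F8	RFC4	ORC6	DHFR	CDC25A	MCM10	PCLAF	FANCI	GINS1	POLE2	TYMSOS	RRM2B
G2	Whitfield-derived G2 phase signature	CCNA2	TOP2A	CDK1	NDC80	CKS2	NUF2	CKS1B	MKI67	TMPO	CENPF	TACC3	SMC4	CCNF	KIF23	HMMR	CENPA	CDC25C	KIF5B	G2E3	CKAP5	FAM64A	HN1	TTK	CENPE
G2M	Whitfield-derived G2/M phase signature	CCNB1	CCNB2	CDC20	PLK1	BUB1	KIF11	ANLN	CDCA8	ECT2	KIF2C	AURKB	BUB1B	CKAP2	TPX2	AURKA	PSRC1	DLGAP5	CDCA2	CDCA3	UBE2C	HJURP	BIRC5	NEK2	GTSE1	KIF20B
MG1	Whitfield-derived M/G1 phase signature	RAD21	CDKN3	PTTG1	ANP32E	CBX3	CTCF	DKC1	DNAJB6	GAS2L3	KIF13A	LBR	MT2A	NUCKS1	NUSAP1	PSMD11	SEPHS1	STAG1	TAF9	TMEM138	TROAP	VPS25	ZNF281
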