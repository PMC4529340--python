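PAM50_USABLE	45 intrinsic genes usable on the platform	ESR1	PGR	FOXA1	NAT1	SLC39A6	MAPT	BCL2	BAG1	BLVRA	MLPH	GPR160	TMEM45B	MDM2	ANLN	BIRC5	CCNB1	CCNE1	CDC20	CDC6	CENPF	CEP55	EXO1	KIF2C	MELK	MKI67	NDC80	PTTG1	RRM2	TYMS	UBE2C	UBE2T	KRT5	KRT14	KRT17	CDH3	FOXC1	SFRP1	EGFR	PHGDH	ACTR3B	ERBB2	GRB7	MYC	MMP11	FGFR4
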