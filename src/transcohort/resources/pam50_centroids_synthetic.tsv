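gene	LumA	LumB	ERBB2	Basal
ESR1	1.0	1.0	-0.5	-1.0
PGR	1.0	1.0	-0.5	-1.0
FOXA1	1.0	1.0	-0.5	-1.0
NAT1	1.0	1.0	-0.5	-1.0
SLC39A6	1.0	1.0	-0.5	-1.0
MAPT	1.0	1.0	-0.5	-1.0
BCL2	1.0	1.0	-0.5	-1.0
BAG1	1.0	1.0	-0.5	-1.0
BLVRA	1.0	1.0	-0.5	-1.0
MLPH	1.0	1.0	-0.5	-1.0
GPR160	1.0	1.0	-0.5	-1.0
TMEM45B	1.0	1.0	-0.5	-1.0
MDM2	1.0	1.0	-0.5	-1.0
ANLN	-1.0	1.0	0.5	1.0
BIRC5	-1.0	1.0	0.5	1.0
CCNB1	-1.0	1.0	0.5	1.0
CCNE1	-1.0	1.0	0.5	1.0
CDC20	-1.0	1.0	0.5	1.0
CDC6	-1.0	1.0	0.5	1.0
CENPF	-1.0	1.0	0.5	1.0
CEP55	-1.0	1.0	0.5	1.0
EXO1	-1.0	1.0	0.5	1.0
KIF2C	-1.0	1.0	0.5	1.0
MELK	-1.0	1.0	0.5	1.0
MKI67	-1.0	1.0	0.5	1.0
NDC80	-1.0	1.0	0.5	1.0
PTTG1	-1.0	1.0	0.5	1.0
RRM2	-1.0	1.0	0.5	1.0
TYMS	-1.0	1.0	0.5	1.0
UBE2C	-1.0	1.0	0.5	1.0
UBE2T	-1.0	1.0	0.5	1.0
KRT5	-1.0	-1.0	-1.0	1.0
KRT14	-1.0	-1.0	-1.0	1.0
KRT17	-1.0	-1.0	-1.0	1.0
CDH3	-1.0	-1.0	-1.0	1.0
FOXC1	-1.0	-1.0	-1.0	1.0
SFRP1	-1.0	-1.0	-1.0	1.0
EGFR	-1.0	-1.0	-1.0	1.0
PHGDH	-1.0	-1.0	-1.0	1.0
ACTR3B	-1.0	-1.0	-1.0	1.0
ERBB2	0.0	0.0	1.0	-0.5
GRB7	0.0	0.0	1.0	-0.5
MYC	0.0	0.0	0.5	0.0
MMP11	0.0	0.0	0.5	0.0
FGFR4	0.0	0.0	0.5	0.0
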