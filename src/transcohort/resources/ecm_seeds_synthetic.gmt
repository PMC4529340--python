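ECM1_SEED	immune/protease ECM cluster markers	CTSS	GZMK	MMP7	MMP9	SELL	SPOCK2	VCAM1
ECM3_SEED	collagen/stromal ECM cluster markers (synthetic signature stand-in)	SPARC	BGN	CDH11	FN1	LAMA4	MMP2	COL1A1	COL1A2	COL5A1	COL5A2	COL5A3	COL6A1	COL6A2	COL6A3
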