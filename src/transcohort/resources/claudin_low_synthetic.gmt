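CLAUDIN_LOW	epithelial+mesenchymal recognition genes (synthetic membership)	CLDN3	CLDN4	CLDN7	CDH1	KRT8	KRT18	EPCAM	VIM	ZEB1	ZEB2	SNAI1	SNAI2	TWIST1	MMP14
CLAUDIN_EPITHELIAL	claudin/E-cadherin epithelial subset	CLDN3	CLDN4	CLDN7	CDH1	KRT8	KRT18	EPCAM
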