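tme_signature_a	+1	CD8A	GZMA	GZMB	PRF1	IFNG	CXCL9	CXCL10	CXCL11	CXCL13	CCL5	CD2	CD3D	CD3E	CD27	IL2RG	NKG7	TBX21	STAT1	IDO1	GBP1	GBP5	IRF1	HLA-DRA	HLA-E	PSMB9
tme_signature_b	-1	FAP	MIR100HG	SYNPO	TGFB1I1	COL1A1	COL4A1	COL5A1	ACTA2	PDGFRB	TAGLN	MYH11	CNN1	ZEB1	TWIST1	SNAI2	VIM	THBS2	SPARC	LUM
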