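LN	lymph-node-like TME archetype, top 20 marker genes	TNFRSF25	SELL	PIK3CD	IL16	BIRC3	CCL21	FOXP3	LY9	KLRB1	CD1C	LTB	CD40LG	LAMC2	SIGLEC5	MYBL1	ICOSLG	ATM	PDK1	C5	FCGR2B
FMAC	follicular-macrophage/accessory-cell TME archetype, top 20 marker genes	CLEC14	CD36	STC1	ANGPTL4	JAG1	PALMD	TIE1	ROBO4	SNAI1	ITGB3	CDH5	BCL6B	MMRN2	SPRY4	KDR	DIPK2B	JAG2	APLNR	TPM1	PDGFB
TEX	T-cell-exhausted TME archetype, top 20 marker genes	IDO1	GZMB	TLR8	GZMH	CCL4	CD244	LAG3	GZMA	CXCR6	FASLG	NKG7	CCR5	PRF1	SLAMF7	GZMK	CD8A	C1QA	C1QB	GBP1	FCGR1A
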