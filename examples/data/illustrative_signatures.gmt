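B_cells	illustrative	CD19	MS4A1	CD79A	CD79B	BLK	TNFRSF13B
CD8_T_cells	illustrative	CD8A	CD8B	GZMK	GZMA	PRF1	CD3D	CD3E
NK_cells	illustrative	NKG7	GNLY	KLRD1	KLRF1	NCR1	KIR2DL3
Macrophages	illustrative	CD68	CD163	MSR1	MRC1	CSF1R	ITGAM
Neutrophils	illustrative	FCGR3B	CSF3R	S100A8	S100A9	CEACAM8
Dendritic_cells	illustrative	ITGAX	CD1C	CLEC9A	BATF3	FLT3
Mast_cells	illustrative	TPSAB1	TPSB2	CPA3	MS4A2	KIT
Th1_cells	illustrative	TBX21	IFNG	IL12RB2	CXCR3	STAT4
Tregs	illustrative	FOXP3	IL2RA	CTLA4	IKZF2	TNFRSF18
Endothelial_cells	illustrative	PECAM1	VWF	CDH5	CLDN5	KDR
Fibroblasts	illustrative	COL1A1	COL1A2	FAP	PDGFRB	THY1
Monocytes	illustrative	CD14	FCN1	S100A12	VCAN	LYZ
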