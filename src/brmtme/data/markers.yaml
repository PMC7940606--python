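# Default curated immune marker genes per cell type.
# A pragmatic, non-canonical working list of widely used lineage markers;
# real analyses should supply their own expert-curated file.
cytotoxic T: [CD3D, CD3E, CD8A, GZMB, GZMA, PRF1, NKG7, CCL5]
naive T: [CD3D, CD3E, CD4, CCR7, LEF1, SELL, TCF7, IL7R]
Treg: [CD3D, CD3E, FOXP3, IL2RA, CTLA4, IKZF2, TNFRSF4]
NK: [NKG7, GNLY, KLRD1, NCAM1, KLRF1, FCGR3A]
TAM/microglia: [CD68, LYZ, AIF1, CD14, C1QA, C1QB, P2RY12, TMEM119]
B cells: [MS4A1, CD79A, CD79B, CD19, IGHM, BANK1]
DC: [FCER1A, CD1C, CLEC9A, LILRA4, ITGAX, BATF3]
neutrophils: [FCGR3B, CSF3R, S100A8, S100A9, CXCR2, FPR1]
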