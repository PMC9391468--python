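hist_mod	cell_type	n_samples	n_peaks	n_motifs
H3K4me3	CD3+CD4+CD8+	3	48295	17
H3K4me3	CD3-CD4+CD8+	2	33132	19
H3K4me3	CD4+ab	1	37452	20
H3K4me3	CD8+ab	1	36825	18
H3K4me1	CD3+CD4+CD8+	1	36308	2
H3K27ac	CD3+CD4+CD8+	2	33131	18
H3K27ac	CD3-CD4+CD8+	1	12334	17
H3K27ac	CD4+ab	1	6011	18
H3K36me3	CD3+CD4+CD8+	2	53760	1
H3K27me3	CD3-CD4+CD8+	1	2333	20
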