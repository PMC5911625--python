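# provenance: published 19-pair thyroid-cancer diagnostic signature (26 genes; training-cohort LASSO fit, lexicographic pair orientation, tumor = positive; published coefficients carry no intercept)
# intercept: 0.0
gene_first	gene_second	coefficient
CA4	CDH3	-0.343957681
CA4	DPP4	-0.414152857
DPP4	SMAD9	0.198178763
GLRB	SEMA3D	0.213058352
GLT8D2	IER2	0.054809905
GLUL	TFF3	0.106305040
HSPA5	TFF3	0.137164218
ID1	TPO	0.133836321
ITIH5	LRP4	-0.449239654
KRT19	LMOD1	0.166685729
KRT19	LRP1B	0.026410689
LMOD1	SLC34A2	-0.134480682
LRP1B	LRP4	-0.180802140
LRP1B	MYEF2	-1.070962895
LRP1B	SLMO1	-0.158658033
LRP4	TNFRSF11B	0.149105475
NELL2	TCEAL2	0.178969566
QPCT	TNFRSF11B	0.692483617
TCEAL2	TRAPPC6A	-0.229715917
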