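receptor	log2fc	fdr	ligands	n_enriched_pathways
PDGFRA	2.68	5.32e-7	PDGFC,PDGFA,PDGFB,PDGFD	15
LGR6	2.27	1.93e-4	RSPO3	1
FPR1	2.05	3.75e-6	SAA1	1
FGFR4	1.97	3.46e-6	FGF5	3
LPR8	1.94	2.23e-7	APOE,LRPAP1,RELN	1
F3	1.82	8.94e-6	IL6,TFPI	5
KDR	1.55	5.09e-3	SEMA6D,TIMP3,VEGFC,VEGFA,COL18A1,PDGFC	17
NOTCH3	1.50	2.81e-3	DLL1,DLL3,THBS2	6
PLXNA2	1.41	2.00e-3	SEMA6A,SEMA3A	1
CELSR1	1.30	2.18e-2	PSAP	1
IL6R	1.28	4.79e-2	IL6	7
VIPR1	1.13	2.86e-2	GNAS	1
SCARB1	1.08	1.89e-2	THBS1,SAA1,APOE	7
LDLR	0.90	2.16e-4	APOE,LRPAP1	10
ITGA3	0.33	1.42e-2	RELN,LAMB3,NID1,LAMC2,LAMC1,LAMB1,ADAM9,LAMA4,FN1,THBS1,CALR,TIMP2,LAMA5,PLAU	6
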