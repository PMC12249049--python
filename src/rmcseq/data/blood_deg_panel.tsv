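gene_id	symbol	log2fc	fdr	classification	biotype
ENSG00000250568	PABPC1	1.2687	0.0267	URG	pseudogene
ENSG00000260035	Lnc-DUOXA1-2	2.3900	0.0003	URG	lncRNA
ENSG00000149925	ALDOA	0.8515	0.0014	URG	protein_coding
ENSG00000141480	ARRB2	0.4655	0.0009	URG	protein_coding
ENSG00000135636	DYSF	0.6159	0.0109	URG	protein_coding
ENSG00000132589	FLOT2	0.4394	0.0369	URG	protein_coding
ENSG00000167996	FTH1	1.1435	0.0024	URG	protein_coding
ENSG00000174021	GNG5	0.4621	0.0295	URG	protein_coding
ENSG00000170837	GPR27	0.6579	0.0127	URG	protein_coding
ENSG00000030582	GRN	0.5643	0.0495	URG	protein_coding
ENSG00000248099	INSL3	1.4028	0.0014	URG	protein_coding
ENSG00000251230	MIR3945HG	0.8796	0.0493	URG	protein_coding
ENSG00000170909	OSCAR	0.5463	0.0403	URG	protein_coding
ENSG00000170525	PFKFB3	0.8153	0.0006	URG	protein_coding
ENSG00000105287	PRKD2	0.4599	0.0077	URG	protein_coding
ENSG00000112053	SLC26A8	0.9719	0.0495	URG	protein_coding
ENSG00000266402	SNHG25	1.6604	0.0156	URG	protein_coding
ENSG00000184292	TACSTD2	3.8049	0.0000	URG	protein_coding
ENSG00000156414	TDRD9	1.1963	0.0403	URG	protein_coding
ENSG00000170873	MTSS1	-0.6198	0.0011	DRG	protein_coding
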