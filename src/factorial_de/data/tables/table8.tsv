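# Table 8 of the source study: enriched functional-category clusters among genes
# differentially expressed between genotypes. The first cluster (printed score 3.59)
# is fully listed; the second (printed score 3.43) is partially listed per the table's
# own footnote filter, so fully_listed is 0 and its score cannot be recomputed.
cluster	printed_score	fully_listed	category	term	n_genes	p	fdr_p
1	3.59	1	KEGG_PATHWAY	mmu05410:Hypertrophic cardiomyopathy (HCM)	10	7.69E-05	0.09
1	3.59	1	KEGG_PATHWAY	mmu04260:Cardiac muscle contraction	9	2.65E-04	0.31
1	3.59	1	KEGG_PATHWAY	mmu05414:Dilated cardiomyopathy	9	8.16E-04	0.96
2	3.43	0	GO_BP_FAT	GO:0007167~enzyme linked receptor protein signaling pathway	20	7.05E-06	0.01
2	3.43	0	GO_BP	GO:0007179~transforming growth factor beta receptor signaling pathway	7	5.38E-04	0.89
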