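# Table 10 of the source study: enriched functional-category clusters among genes
# differentially expressed between activity levels (printed scores 19.79 and 8.42).
# Both clusters are fully listed. Member P-values are printed to 3 significant figures,
# which limits score recomputation to ~0.01.
cluster	printed_score	fully_listed	category	term	n_genes	p	fdr_p
1	19.79	1	KEGG_PATHWAY	mmu00190:Oxidative phosphorylation	51	5.29E-29	6.39E-26
1	19.79	1	KEGG_PATHWAY	mmu05012:Parkinson's disease	50	2.05E-27	2.47E-24
1	19.79	1	GOTERM_BP_FAT	GO:0006091~generation of precursor metabolites and energy	65	2.35E-27	4.12E-24
1	19.79	1	KEGG_PATHWAY	mmu05010:Alzheimer's disease	55	7.43E-25	8.98E-22
1	19.79	1	KEGG_PATHWAY	mmu05016:Huntington's disease	53	5.65E-23	6.82E-20
1	19.79	1	GOTERM_BP_FAT	GO:0022900~electron transport chain	39	4.30E-22	7.54E-19
1	19.79	1	GOTERM_MF_FAT	GO:0015078~hydrogen ion transmembrane transporter activity	23	4.07E-11	6.28E-08
1	19.79	1	GOTERM_MF_FAT	GO:0015077~monovalent inorganic cation transmembrane transporter activity	23	1.44E-10	2.22E-07
1	19.79	1	GOTERM_MF_FAT	GO:0022890~inorganic cation transmembrane transporter activity	26	2.46E-09	3.79E-06
2	8.42	1	KEGG_PATHWAY	mmu04260:Cardiac muscle contraction	28	1.13E-14	1.35E-11
2	8.42	1	GOTERM_MF_FAT	GO:0015078~hydrogen ion transmembrane transporter activity	23	4.07E-11	6.28E-08
2	8.42	1	GOTERM_MF_FAT	GO:0015077~monovalent inorganic cation transmembrane transporter activity	23	1.44E-10	2.22E-07
2	8.42	1	GOTERM_MF_FAT	GO:0022890~inorganic cation transmembrane transporter activity	26	2.46E-09	3.79E-06
2	8.42	1	GOTERM_MF_FAT	GO:0016675~oxidoreductase activity, acting on heme group of donors	10	7.32E-07	1.13E-03
2	8.42	1	GOTERM_MF_FAT	GO:0016676~oxidoreductase activity, acting on heme group of donors, oxygen as acceptor	10	7.32E-07	1.13E-03
2	8.42	1	GOTERM_MF_FAT	GO:0015002~heme-copper terminal oxidase activity	10	7.32E-07	1.13E-03
2	8.42	1	GOTERM_MF_FAT	GO:0004129~cytochrome-c oxidase activity	10	7.32E-07	1.13E-03
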