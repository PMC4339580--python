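# Table 4 of the source study: the single enriched functional-category cluster
# (printed enrichment score 16.28) among genes under-expressed in the AW-IM and AM-IM
# contrasts and not differentially expressed elsewhere. One row per member term with
# its DAVID EASE P-value and FDR-adjusted P-value.
category	term	n_genes	p	fdr_p
KEGG_PATHWAY	mmu00190:Oxidative phosphorylation	31	6.69E-33	6.84E-30
KEGG_PATHWAY	mmu05012:Parkinson's disease	30	6.01E-31	6.14E-28
GOTERM_BP_FAT	GO:0022900~electron transport chain	24	1.58E-27	2.39E-24
KEGG_PATHWAY	mmu05010:Alzheimer's disease	30	9.82E-27	1.00E-23
KEGG_PATHWAY	mmu05016:Huntington's disease	30	1.16E-26	1.19E-23
GOTERM_BP_FAT	GO:0006091~generation of precursor metabolites and energy	29	2.84E-25	4.30E-22
GOTERM_BP_FAT	GO:0055114~oxidation reduction	32	3.95E-17	5.99E-14
GOTERM_MF_FAT	GO:0015078~hydrogen ion transmembrane transporter activity	12	1.27E-11	1.65E-08
GOTERM_MF_FAT	GO:0015077~monovalent inorganic cation transmembrane transporter activity	12	2.47E-11	3.20E-08
GOTERM_MF_FAT	GO:0022890~inorganic cation transmembrane transporter activity	12	1.55E-09	2.01E-06
KEGG_PATHWAY	mmu04260:Cardiac muscle contraction	10	2.24E-07	2.29E-04
GOTERM_MF_FAT	GO:0015002~heme-copper terminal oxidase activity	6	5.10E-07	6.61E-04
GOTERM_MF_FAT	GO:0016675~oxidoreductase activity, acting on heme group of donors	6	5.10E-07	6.61E-04
GOTERM_MF_FAT	GO:0016676~oxidoreductase activity, acting on heme group of donors, oxygen as acceptor	6	5.10E-07	6.61E-04
GOTERM_MF_FAT	GO:0004129~cytochrome-c oxidase activity	6	5.10E-07	6.61E-04
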