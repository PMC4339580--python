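# Table 7 of the source study: the 13 genes differentially expressed between
# myostatin-reduced and wild-type mice (FDR-adjusted P <= 0.005, |log2FC| >= 1.3),
# excluding genes with significant interaction. lfc is log2(myostatin-reduced/wild-type).
gene	lfc	fdr_p
ERCC2	4.19	2.5E-03
DGCR8	4.09	2.5E-03
METTL21E	3.48	2.5E-03
GSPT1	2.38	2.5E-03
ACTC1	2.29	2.5E-03
GREM2	1.91	2.5E-03
SLN	1.89	2.5E-03
CDH4	1.88	2.5E-03
F830016B08RIK	1.87	2.5E-03
KATNAL2	1.74	2.5E-03
IL12A	1.47	2.5E-03
MYBPH	1.34	2.5E-03
VASH2	1.30	2.5E-03
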