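# Table 9 of the source study: the 21 genes differentially expressed between active and
# inactive mice (FDR-adjusted P <= 0.005, |log2FC| >= 1.3), excluding genes with
# significant interaction. lfc is log2(active/inactive).
gene	lfc	fdr_p
ERCC2	3.95	1.54E-03
BDH1	2.38	1.54E-03
GM1078	2.28	1.54E-03
BC048679	2.28	1.54E-03
LRRC52	1.92	1.54E-03
LDHB	1.88	1.54E-03
TNNC1	1.86	1.54E-03
EGLN3	1.82	1.54E-03
MYL2	1.82	1.54E-03
TNNT1	1.78	1.54E-03
MYH7	1.78	1.54E-03
MYOM3	1.76	1.54E-03
ESRRB	1.74	1.54E-03
SLC26A10	1.65	1.54E-03
FHL2	1.65	1.54E-03
ANKRD2	1.63	1.54E-03
MYH2	1.61	1.54E-03
TM6SF1	1.59	1.54E-03
IQSEC2	1.57	1.54E-03
VAV2	1.53	1.54E-03
TPM3	1.51	1.54E-03
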