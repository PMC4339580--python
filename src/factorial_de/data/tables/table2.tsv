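# Table 2 of the source study: differentially expressed genes shared between the three
# orthogonal contrasts against the inactive wild-type (IW) baseline group, with log2
# fold changes (contrast "A-B" reports log2(B/A)). The printed table lists 34 rows; the
# M6prbp1 row appears twice, leaving 33 unique genes.
gene	IW-AW	IW-AM	IW-IM
M6prbp1	-0.55	-0.92	0.47
Pak1	-0.60	-1.16	1.07
Casq2	-0.87	-1.25	-0.75
Fos	0.79	1.57	-1.53
Dhrs4	-0.63	-0.64	-0.60
Gm5514	-1.44	-1.21	-1.52
Ddah1	0.59	2.23	-2.15
Fabp3	-0.75	-0.63	-0.93
Got1	-0.62	-0.55	-0.44
2310076L09Rik	-0.87	-0.72	-1.04
Mafb	-0.78	-1.07	0.58
EG225594	-1.64	-1.55	2.22
4832428D23Rik	-1.20	-3.91	4.48
BDH1	-1.83	-1.47	-2.24
ZMYND11	0.85	2.10	-1.63
Gck	1.17	1.48	-0.70
Esrrb	-1.26	-1.28	-1.28
Acaa2	-0.59	-0.53	-0.69
Ankrd2	-1.18	-0.92	-1.59
Actn2	-0.62	-0.78	-0.87
Egr1	1.56	1.65	-1.48
Myom3	-1.13	-1.08	-1.93
9830123M21Rik	0.69	2.52	-0.49
Rn45s	-0.80	-1.94	1.16
NNT	-0.79	-0.72	-0.70
Dgat2	-0.83	-0.70	-0.97
H19	-0.68	-0.89	0.43
Tbc1d1	0.72	0.98	-0.91
IL15	-1.05	-1.39	1.06
Myh2	-1.08	-0.85	-1.78
COL22A1	0.63	0.74	-0.48
ORF63	0.85	0.93	-0.75
IDH2	-0.85	-0.67	-0.92
M6prbp1	-0.55	-0.92	0.47
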