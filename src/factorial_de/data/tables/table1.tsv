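# Table 1 of the source study: genes with the most significant activity-by-genotype
# interaction, with log2 fold changes for the six pairwise contrasts (contrast "A-B"
# reports log2(B/A)) and the overall FDR-adjusted interaction P-value. The footnote_mode
# column carries the table's italic synergistic/antagonistic annotations.
gene	AM-AW	AM-IM	AW-IM	IW-IM	IW-AW	IW-AM	fdr_p	footnote_mode
Mettl21e	2.72	0.57	3.29	4.48	-1.19	-3.91	1.55E-13	antagonistic
Dusp18	-0.78	-0.73	-1.51	-0.64	-0.87	-0.09	1.55E-13	.
Per1	1.22	0.40	1.62	0.82	0.79	-0.42	1.55E-13	.
Atp1b2	0.62	0.34	0.96	0.31	0.65	0.023	1.55E-13	.
Tnnc1	-0.89	-4.14	-5.03	-3.67	-1.36	-0.47	1.55E-13	.
Zmynd17	-1.25	0.47	-0.78	-1.63	0.85	2.09	1.55E-13	.
Myh7	-0.72	-4.87	-5.58	-4.37	-1.20	-0.49	1.55E-13	.
Tpm3	-0.75	-2.22	-2.96	-1.76	-1.20	-0.46	1.55E-13	.
Ddah1	-1.64	0.08	-1.57	-2.15	0.59	2.23	1.55E-13	synergistic
Myl2	-1.15	-3.74	-4.89	-3.49	-1.39	-0.25	1.55E-13	.
Atp2a2	-0.89	-2.15	-3.05	-2.31	-0.74	0.16	1.55E-13	.
Pak1	0.56	-0.09	0.46	1.07	-0.60	-1.16	1.55E-13	antagonistic
Tnnt1	-0.92	-4.07	-4.99	-3.66	-1.33	-0.41	1.55E-13	.
Csrp3	-0.91	-1.92	-2.83	-2.01	-0.82	0.09	1.55E-13	.
Fxyd6	-0.76	-2.05	-2.81	-1.96	-0.85	-0.08	1.55E-13	.
Myoz2	-0.59	-2.43	-3.03	-2.12	-0.91	-0.31	6.84E-13	.
Myl3	-0.62	-3.15	-3.77	-2.76	-1.01	-0.39	6.84E-13	.
Naca	0.87	0.03	0.91	0.43	0.48	-0.39	1.89E-12	.
Ak3	0.55	-1.53	-0.99	0.41	-1.40	-1.95	1.89E-12	.
Cyp1a1	2.04283	-0.84607	1.19676	0.267273	0.929775	-1.11319	3.16E-12	.
Grem2	1.44986	0.213147	1.66277	2.52511	-0.86228	-2.31217	3.16E-12	antagonistic
Fos	-0.78073	0.039794	-0.74082	-1.52664	0.786004	1.56659	8.48E-12	synergistic
Gnb2l1	0.739797	-0.36408	0.375364	-0.32355	0.699348	-0.04009	8.56E-12	.
Wnk2	1.10552	0.056718	1.16275	0.760786	0.402344	-0.70346	2.45E-11	.
Tmem100	-0.76578	0.050259	-0.71569	-1.11695	0.401146	1.16691	3.02E-11	synergistic
Ncor2	0.556591	-0.14625	0.41082	-0.02854	0.439626	-0.11714	6.96E-11	.
Acta2	0.972604	-0.62395	0.348594	-0.39031	0.738874	-0.23374	2.01E-10	.
Pmepa1	-0.67603	-0.0258	-0.70168	-1.02573	0.324245	1.00005	2.01E-10	synergistic
Sln	1.5134	0.156663	1.67004	2.36704	-0.69664	-2.21015	2.90E-10	antagonistic
Dhcr24	0.771441	-0.05624	0.715401	-0.12054	0.83638	0.064728	3.20E-10	.
Dusp23	0.468437	0.024808	0.493519	0.026371	0.467286	-0.00141	1.01E-09	.
Ramp1	-0.66605	-0.05061	-0.71666	-0.92948	0.213069	0.87899	1.07E-09	.
Atrnl1	-0.67904	-0.04955	-0.72883	-0.49233	-0.2365	0.442585	1.32E-09	.
Lancl1	-1.22412	0.08892	-1.13543	-1.33056	0.195232	1.41926	1.43E-09	synergistic
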