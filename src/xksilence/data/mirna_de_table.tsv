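id	group	total_count	mature_seq	log2fc_crwr	sig_crwr	log2fc_ddcl1	sig_ddcl1	log2fc_ddcl2	sig_ddcl2
cro-mir-1	fungal	68544	UAGAAUUCGGGGUAGAAU	-1.83	1	-0.07	0	-5.84	1
cro-mir-2	fungal	2032	UAGAAUUCGGGGUAGAAUG	-2.73	1	0.49	0	-4.35	1
cro-mir-3	fungal	33147	UUAGCCUCGAGACUUUGCA	-3.74	1	0.27	0	-4.49	1
cro-mir-4	fungal	1994	UCAGCCUCGAGACUUUGCC	-2.92	1	0.77	0	-6.01	1
cro-mir-10	fungal	875	UCGGUGGGAUGUUUGAGACU	-4.74	1	1.11	0	-3.09	1
cro-mir-11	fungal	955	UAGAGUUUUUGGAGAUGCU	-2.42	1	0.49	0	-6.38	1
cro-mir-363	fungal	2160	UCAAACACAAUUAGCGGUC	-1.9	1	0.78	0	-6.02	1
cro-mir-73	fungal	48980	UCUGAAGGUCGUGUGUUC	5.65	1	-2.69	1	-2.74	1
cro-mir-77	fungal	683	UAUGCCUAGGCUUGUGCGA	-3.54	1	-0.93	0	-4.9	1
cro-mir-5	fungal	94	UUGCAAUGAUUUGCAUUUCGC	-3.76	1	-2.17	0	-0.88	0
cro-mir-6	fungal	1875	UAGGACUCGAGUAGUUAUAAC	-5	1	0.94	0	-2.47	0
cro-mir-9	fungal	447	UCGGACGUAUAUUGACUACUC	-3.79	1	-0.95	0	-4.05	0
cro-mir-13	fungal	11099	UUCUUCCUUGAUGCGUCCC	-4.62	1	0.11	0	-3.85	0
cro-mir-30	fungal	187	UGCCUGUCUGAGCGUCAUU	-2.9	1	2.15	0	1.12	0
cro-mir-74	fungal	460	CACGAUGUCCCGUAUCCGACGU	-2.78	1	-0.73	0	-3.21	0
cro-mir-76	fungal	700	UGUUUCUUUGUUUUUGCCU	-4.14	1	0.97	0	-2.46	0
mir_12061_x13	wheat	122	UGUAGAUACUCCCUAAGGCUU	-1.98	1	1.71	1	0.01	0
mir_18750_x1	wheat	112	UGUAGAUACUCUCUAAGGCUU	-2.53	1	2.22	1	0.48	0
mir_16010_x2	wheat	114	UGUAGAUACUCCCUAAGGCU	-2.32	1	2.01	1	0.27	0
mir_17532_x1	wheat	118	UGUAGAUACUCCCUAGGGCUU	-2.23	1	1.96	1	0.15	0
mir_19460_x1	wheat	125	CACCAACCGGUACUAAUGGGCAUC	-2.01	1	2.1	1	1.55	0
mir_13110_x8	wheat	172	UCGGACCAGGCUUCAUUCCUU	-1.51	1	1.48	0	0.68	0
mir_18139_x1	wheat	179	CGCCCCACGGUGGGCGCCA	1.65	1	-0.8	0	-0.74	0
mir_16988_x1	wheat	296	GUGGAUGAUGAGAUCACAAGUAA	1.75	1	-0.52	0	-0.95	0
mir_15432_x2	wheat	140	GCCCCACGGUGGGCGCCA	2.34	1	-0.74	0	-1.1	0
mir_13653_x6	wheat	10902	GCCCGUCUAGCUCAGUUGGU	0.25	0	-1.68	1	-1.5	1
mir_16507_x1	wheat	83527	CCGACCUUAGCUCAGUUGGU	0.32	0	-1.51	1	-1.31	0
mir_18684_x1	wheat	201	GACCUGUAUGGGGCACCA	0.69	0	-1.9	1	-0.93	0
mir_19043_x1	wheat	3970	AACCUUGUGGUCGUGGGUUC	0.95	0	-1.76	1	-1.39	0
mir_15848_x2	wheat	30986	CCCGCCUUGCACCAAGUGAAU	-0.36	0	1.54	1	0.83	0
mir_16416_x1	wheat	153	CAUCUCUCCUGUAGAAAUAGGCAC	-0.8	0	1.56	1	0.9	0
mir_17663_x1	wheat	8712	UUUCCCGGCUAGUGCACC	-0.51	0	-0.44	0	1.58	1
mir_16687_x1	wheat	1322	AACUACAAUCUGAGGCUU	-0.71	0	0.11	0	2.42	1
mir_18451_x1	wheat	689	CCACAGGCUUUCUUGAACUG	-0.43	0	0.12	0	2.51	1
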