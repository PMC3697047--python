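id	sequence	x2	x3	delta	rhhk_f3	sigma	yrhb_f4
hsa-mir-342	uCUCACACAGAAAUCGCACCCGU	7.81	4.85	1.48	1.95	6.33	0.77
hsa-mir-21	UAGCUUAUCAGACUGAUGUUGA	8.34	7.24	0.55	1.59	7.79	1.45
hsa-mir-378	ACUGGACUUGGAGUCAGAAGGC	4.97	5.89	-0.46	1.26	5.43	0.00
hsa-mir-629	GUUCUCCCAACGUAAGCCCAGC	5.28	7.98	-1.35	0.91	6.63	0.37
hsa-mir-92b	UAUUGCACUCGUCCCGGCCUCC	6.48	8.98	-1.25	0.22	7.73	1.06
hsa-mir-221	AGCUACAUUGUCUGCUGGGUUU	6.08	5.26	0.41	2.37	5.67	0.50
hsa-mir-29c	UAGCACCAUUUGAAAUCGGUUA	6.08	6.05	0.02	1.36	6.06	0.42
hsa-mir-210	CUGUGCGUGUGACAGCGGCUGA	6.81	7.96	-0.57	0.59	7.38	1.32
hsa-mir-let7d	CUAUACGACCUGCUGCCUUUCU	6.49	6.46	0.01	1.53	6.47	1.00
hsa-mir-99b	CACCCGUAGAACCGACCUUGCG	8.55	6.70	0.92	1.43	7.62	2.09
hsa-mir-191	CAACGGAAUCCCAAAAGCAGCU	6.40	7.47	-0.53	1.05	6.94	0.82
hsa-mir-425	aAUGACACGAUCACUCCCGUUGA	7.33	8.50	-0.59	0.10	7.92	1.99
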