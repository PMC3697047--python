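id	sequence	activity	wrhw_f1	dryd_f2
ath-mir-156	UGACAGAAGAGAGUGAGCAC	3.09	0.97	2.08
ath-mir-157	UUGACAGAAGAUAGAGAGCAc	1.72	1.89	1.02
ath-mir-158	UCCCAAAUGUAGACAAAGCA	4.85	1.79	2.01
ath-mir-159	UUUGGAUUGAAGGGAGCUCUa	5.21	1.30	1.40
ath-mir-160	UGCCUGGCUCCCUGUAUGCCa	3.81	0.69	2.43
ath-mir-161.1	UGAAAGUGACUACAUCGGGGt	4.68	1.22	1.87
ath-mir-161.2	UCAAUGCAUUGAAAGUGACUa	3.90	1.78	1.63
ath-mir-163	UUGAAGAGGACUUGGAACUUcgau	1.96	0.61	1.70
ath-mir-164	UGGAGAAGCAGGGCACGUGCa	4.24	1.64	1.46
ath-mir-165	UCGGACCAGGCUUCAUCCCCc	0.90	0.00	0.70
ath-mir-166	UCGGACCAGGCUUCAUUCCCc	1.48	0.00	0.70
ath-mir-168	UCGCUUGGUGCAGGUCGGGAa	4.02	1.00	1.25
ath-mir-169	CAGCCAAGGAUGACUUGCCGa	2.11	0.00	1.61
ath-mir-171	UGAUUGAGCCGCGCCAAUAUc	2.02	0.48	1.17
ath-mir-390	AAGCUCAGGAGGGAUAGCGCc	2.65	0.43	2.13
ath-mir-394	UUGGCAUUCUGUCCACCUCC	2.00	0.00	0.25
ath-mir-398	UGUGUUCUCAGGUCACCCCUg	1.74	0.57	0.35
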