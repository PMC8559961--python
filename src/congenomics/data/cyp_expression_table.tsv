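accession	cyp	mrna_sp_rock	protein_sp_rock	mrna_ckr_rock	protein_ckr_rock	annotated
AAEL026582	CYP6AA6	1.74	1.03	1.2	0.6	1
AAEL014893	CYP6BB2	2.94	2.19	1.63	0.55	1
AAEL003748	CYP9AE1	2.12	0.57	2.28	0.7	1
AAEL014614	CYP9J10	2.38	1.55	2.04	1.05	1
AAEL006784	CYP9J17	2.09	0.98	1.38	0.55	1
AAEL014609	CYP9J26	3.13	1.59	2.23	0.74	1
AAEL026665	CYP9J27	3.14	2.12	2.37	1.03	1
AAEL014617	CYP9J28	3.94	1.05	4.25	0.99	1
AAEL025530	CYP9M5	4.48	1.39	2.89	0.63	1
AAEL001312	CYP9M6	3.32	2.16	2.14	1.18	1
AAEL006805	CYP9J2	1.44	1.16		0.66	1
AAEL009018	CYP6CB1		1.23		0.54	1
AAEL014618	CYP9J18		0.82		0.96	1
AAEL028635	CYP9J19		0.79		0.82	1
AAEL014619	CYP9J22		0.6		0.54	1
EAT33129.1	CYP9J7		0.94		0.67	0
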