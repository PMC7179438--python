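compound_id	code	role	ec50_nM	pec50	MV	MP	NA	PF	HG	AR
22	BDBM35804	test	2.12	8.67366	1383.25	50.59	64	22	3	3
23	BDBM50079321	test	4.89	8.31069	1487.30	54.92	70	18	1	3
24	BDBM50026816	test	5.86	8.23210	1834.39	66.65	81	27	4	4
25	BDBM50078426	test	9.75	8.01100	1042.47	36.00	45	19	2	3
26	BDBM50079322	test	10.16	7.99311	1395.70	52.90	70	18	1	3
27	BDBM21220	test	12.58	7.90032	855.09	29.13	38	15	1	2
28	BDBM50385958	test	12.00	7.92082	1218.48	43.81	56	18	2	3
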