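compound_id	code	role	ec50_nM	pec50	MV	MP	NA	PF	HG	AR
1	UK-432097	training	0.66	9.18046	2155.82	82.39	104	26	3	5
2	BDBM50385948	training	0.85	9.07058	1379.46	52.03	64	19	3	4
3	BDBM50150762	training	1.40	8.85387	1393.64	51.53	67	25	3	3
4	BDBM50150765	training	1.60	8.79588	1381.93	51.69	63	23	2	3
5	BDBM50385955	training	2.02	8.69465	1317.10	50.20	61	20	3	5
6	BDBM50150764	training	3.10	8.50864	1420.28	51.69	65	26	2	4
7	BDBM50385957	training	5.60	8.25181	846.19	29.04	38	16	1	3
8	BDBM50385950	training	6.30	8.20066	1755.00	68.15	84	23	4	5
9	BDBM50385947	training	6.60	8.18046	1738.51	65.16	81	24	4	3
10	BDBM50150767	training	8.00	8.09691	1361.57	49.70	64	25	2	3
11	BDBM50150766	training	8.80	8.05552	1339.60	49.06	63	23	2	3
12	BDBM50385958	training	12.00	7.92082	1205.69	43.81	56	19	2	4
13	BDBM50385943	training	14.00	7.85387	1243.14	45.16	58	20	2	4
14	BDBM50385946	training	14.00	7.85387	1895.57	72.06	95	38	16	5
15	BDBM50385944	training	42.00	7.37675	1271.34	46.44	56	18	2	3
16	BDBM50385945	training	45.00	7.34679	1876.10	71.43	94	36	16	5
17	BDBM50385949	training	66.00	7.18046	1720.20	66.80	82	22	4	5
18	BDBM50385954	training	89.70	7.04721	2257.04	88.15	107	28	6	5
19	BDBM50150763	training	97.00	7.01323	1371.19	50.99	63	24	2	4
20	BDBM50385952	training	366.00	6.43652	2393.81	94.42	120	39	18	6
21	BDBM50385956	training	2242.00	5.64936	2352.49	93.22	118	41	18	6
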