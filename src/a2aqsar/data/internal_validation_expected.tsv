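compound_id	tetra	tetra_residual	penta	penta_residual	hexa	hexa_residual	experimental	outlier
1	8.98294818	0.197512	9.12779843	0.052662	8.642608925	0.537851	9.18046	0
2	6.99156978	2.07901	7.13790683	1.932673	6.762230924	2.308349	9.07058	1
3	8.27890486	0.574965	8.12289461	0.730975	7.763229123	1.090641	8.85387	1
4	7.20833204	1.587548	6.98392019	1.81196	6.623110462	2.17277	8.79588	1
5	6.4390024	2.255648	6.3982794	2.296371	5.974691405	2.719959	8.69465	1
6	8.39284814	0.115792	8.11686529	0.391775	7.793326136	0.715314	8.50864	0
7	7.76172650	0.490083	7.8997063	0.352104	7.565734821	0.686075	8.25181	0
8	6.92233110	1.278329	6.94590035	1.25476	6.46444254	1.736217	8.20066	1
9	8.10517950	0.075281	8.2346837	-0.054224	7.958933784	0.221526	8.18046	0
10	8.45979122	-0.362881	8.24137752	-0.144468	7.887637662	0.209272	8.09691	0
11	8.27402464	-0.218505	8.18126794	-0.125748	7.819516242	0.236004	8.05552	0
12	7.91841568	0.002404	8.05102783	-0.130208	7.691452796	0.229367	7.92082	0
13	8.11225228	-0.258382	8.20539668	-0.351527	7.844506896	0.009363	7.85387	0
14	7.56453846	0.289332	7.54459856	0.309271	7.402379418	0.451491	7.85387	0
15	7.30993500	0.066815	7.4768018	-0.100052	7.194105882	0.182644	7.37675	0
16	7.42057922	-0.073789	7.53430987	-0.18752	7.389967518	-0.043178	7.34679	0
17	6.78045040	0.40001	6.8531334	0.327327	6.37965774	0.800802	7.18046	0
18	7.04603034	0.00118	7.04921319	-0.002003	6.619084889	0.428125	7.04721	0
19	7.50229980	-0.48907	7.23382085	-0.220591	6.856821156	0.156409	7.01323	0
20	6.34535314	0.091167	6.41080264	0.025717	6.027298653	0.409221	6.43652	0
21	5.96752642	-0.318166	5.79898512	-0.149625	5.399238413	0.250122	5.64936	0
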