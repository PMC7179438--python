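compound_id	code	role	ec50_nM	pec50	MV	MP	NA	PF	HG	AR
ZINC00000416	ZINC00000416	screening			990.05	37.00	48	13	3	2
10002403	10002403	screening			1188.63	44.45	57	15	4	3
5193875	5193875	screening			1141.29	43.64	52	13	4	3
6942649	6942649	screening			802.06	32.34	32	11	0	4
7928320	7928320	screening			1144.49	43.24	50	12	3	3
ZINC04257548	ZINC04257548	screening			1183.02	44.36	57	19	1	3
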