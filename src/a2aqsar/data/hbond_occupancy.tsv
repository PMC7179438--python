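ligand	residue	occupancy_percent	mean_distance_A
UK-432097	THR88	72	3.1
UK-432097	GLU169	79	3.1
UK-432097	HIS397	98	2.9
UK-432097	TYR418	98	2.7
UK-432097	HIS425	84	2.9
UK-432097	ASN400	98	2.9
5193875	GLU169	21	2.7
5193875	LEU396	24	3.0
5193875	ASN400	32	2.9
Regadenoson	TYR9	11	3.2
Regadenoson	GLU13	97	2.6
Regadenoson	GLU169	29	2.8
Regadenoson	HIS397	47	3.0
6942649	GLU13	43	2.8
6942649	ALA63	10	2.9
6942649	SER67	11	3.1
ZINC00000416	ASN181	20	3.1
ZINC00000416	ASN400	25	3.1
ZINC00000416	SER424	33	2.9
7928320	SER67	16	2.9
7928320	ASN181	87	2.9
7928320	HIS425	11	3.0
10002403	HIS425	59	2.8
10002403	ASN400	75	2.9
ZINC04257548	PHE168	31	2.9
ZINC04257548	GLU169	77	3.0
ZINC04257548	ASP170	26	2.7
ZINC04257548	HIS425	98	2.9
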