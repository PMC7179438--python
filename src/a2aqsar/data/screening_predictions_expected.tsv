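compound_id	tetra	penta	hexa
ZINC00000416	6.72890	7.16159	6.78904
10002403	7.05978	7.54407	7.21051
5193875	5.63389	6.06614	5.74906
6942649	3.35970	3.16129	2.66112
7928320	5.69190	6.14174	5.84216
ZINC04257548	7.43343	7.38310	6.89273
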