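ligand	vdw_mean	vdw_sem	ele_mean	ele_sem	gb_mean	gb_sem	np_mean	np_sem	bind_mean	bind_sem
Regadenoson	-51.85	0.18	-20.22	0.37	59.03	0.22	-33.02	0.01	-46.06	0.25
UK-432097	-49.78	0.23	-31.63	0.44	41.03	0.32	-11.23	0.01	-51.61	0.28
ZINC00000416	-47.88	0.15	-23.78	0.24	36.43	0.14	-6.84	0.01	-42.07	0.19
10002403	-48.16	0.20	-21.59	0.32	35.70	0.24	-6.50	0.01	-40.55	0.25
5193875	-48.62	0.15	-7.92	0.21	23.69	0.15	-7.51	0.01	-40.36	0.18
6942649	-28.31	0.15	-23.15	0.31	24.51	0.39	-6.44	0.01	-33.39	0.22
7928320	-45.57	0.18	-33.31	0.43	46.36	0.31	-6.44	0.01	-38.96	0.20
ZINC04257548	-49.83	0.19	-42.54	0.55	58.17	0.37	-7.15	0.01	-41.35	0.22
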