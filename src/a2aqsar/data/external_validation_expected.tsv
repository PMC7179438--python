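compound_id	code	tetra	tetra_residual	penta	penta_residual	hexa	hexa_residual	experimental
22	BDBM35804	8.10378	0.56982	8.17729	0.49631	7.89214	0.78146	8.6736
23	BDBM50079321	8.59992	-0.28932	8.92832	-0.61772	8.51537	-0.20477	8.3106
24	BDBM50026816	8.91106	-0.67896	8.98461	-0.75251	8.85516	-0.62306	8.2321
25	BDBM50078426	7.96806	0.04284	8.06957	-0.05867	7.85361	0.15729	8.0109
26	BDBM50079322	8.25996	-0.26686	8.4744	-0.4813	7.91206	0.08104	7.9931
27	BDBM21220	7.87135	0.02895	8.11297	-0.21267	7.80671	0.09359	7.9003
28	BDBM50385958	8.16918	-0.24838	8.42937	-0.50857	8.11924	-0.19844	7.9208
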