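ligand	ki_nM	deltaG_exp_kcal_mol	docking_kcal_mol
UK-432097	4.00	-11.45	-10.00
UK-432097	4.75	-11.35	-10.00
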