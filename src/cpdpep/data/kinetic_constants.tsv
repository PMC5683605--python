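enzyme_form	enzyme_conc_nM	km_uM	km_se	kcat_per_s	kcat_se	kcat_over_km	kcat_over_km_se
rhCPD	2.5	153	16	12.5	0.5	0.082	0.012
domain_I_active_E762Q	5.0	319	37	8.5	0.5	0.027	0.003
domain_II_active_E350Q	20.0	844	139	7.0	0.9	0.008	0.001
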