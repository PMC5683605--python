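precursor	sequence	z	t	obs_m	theor_m	ppm	r_100nM	r_10nM	r_1nM	r_0.1nM
Thyroglobulin	QQAAALAK	2	2	799.46	799.46	-4	<0.10	0.68	0.95	1.08
Thyroglobulin	FPLGESFLAAK	2	2	1178.64	1178.63	12	<0.10	0.94	1.12	1.09
alpha-Hemoglobin	VDPVNFK	2	2	817.43	817.43	2	<0.10	0.87	1.03	1.06
Thyroglobulin	GQEFTITGQKR	3	2	1263.67	1263.66	11	<0.10	0.75	0.96	0.95
Bovine-serum-albumin	ADLAK	2	2	516.28	516.29	-14	0.11	0.83	1.0	1.11
Thyroglobulin	KFEK	2	3	550.29	550.31	-38	0.11	0.67	0.85	1.07
Thyroglobulin	SLSLK	2	2	546.33	546.34	-15	0.13	0.89	0.98	1.13
Thyroglobulin	LPESK	2	2	572.32	572.32	-8	0.14	0.64	0.49	1.07
Thyroglobulin	KFEKLPESK	2	4	1104.61	1104.62	-5	0.15	0.66	0.96	1.19
Thyroglobulin	LTDEELAFPPLSPSR	2	1	1670.88	1670.85	20	0.16	0.78	1.10	1.07
Bovine-serum-albumin	LVNELTEFAK	2	2	1162.63	1162.62	12	0.20	0.94	1.09	1.09
alpha-Hemoglobin	LRVDPVNFK	3	2	1086.63	1086.62	13	0.21	0.88	1.09	1.06
Bovine-serum-albumin	LVTDLTK	2	2	788.47	788.46	9	0.40	0.84	1.05	1.08
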