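precursor	sequence	z	t	obs_m	theor_m	ppm	r_rhcpd	r_domain_i_active	r_domain_ii_active	r_di_dii
Thyroglobulin	GQEFTITGQKR	2	2	1263.66	1263.66	4	<0.10	<0.10	0.16	<0.10
alpha-Hemoglobin	VDPVNFK	2	2	817.42	817.43	-20	<0.10	1.05	<0.10	>5.00
Thyroglobulin	FAATSFR	2	1	798.40	798.40	-3	0.12	<0.10	0.24	<0.10
Bovine-serum-albumin	LVNELTEFAK	2	2	1162.62	1162.62	1	0.27	0.65	<0.10	>5.00
Bovine-serum-albumin	LVTDLTK	2	2	788.45	788.46	-16	0.33	0.83	0.29	3.53
alpha-Hemoglobin	LRVDPVNFK	3	2	1086.57	1086.62	-44	0.34	1.09	<0.10	>5.00
Bovine-serum-albumin	KQTALVELLK	3	3	1141.66	1141.71	-41	0.42	1.09	0.42	2.60
Bovine-serum-albumin	AEFVEVTK	2	2	921.48	921.48	0	0.43	0.75	0.41	1.84
Thyroglobulin	KVVLQDR	2	2	856.49	856.51	-18	0.54	0.52	0.66	0.86
Thyroglobulin	AFLGTVR	2	1	762.44	762.44	5	0.59	0.56	0.53	1.07
Bovine-serum-albumin	KVPQVSTPTLVEVSR	3	2	1639.00	1638.93	41	0.59	0.96	0.51	1.86
Thyroglobulin	VVLQDR	2	1	728.42	728.42	0	0.64	0.79	0.79	1.00
Thyroglobulin	AVKQFEESQGR	3	2	1277.64	1277.64	3	0.64	0.75	0.75	1.00
Thyroglobulin	AISVPEDIAR	2	1	1069.63	1069.58	46	0.65	0.69	0.59	1.18
Thyroglobulin	ASGLGAAAGQR	2	1	957.52	957.50	17	0.72	0.56	0.83	0.67
Thyroglobulin	GQEIPGTR	2	1	856.47	856.44	33	0.72	0.59	0.59	1.00
Bovine-serum-albumin	IETMR	2	1	648.31	648.33	-26	0.74	0.59	0.74	0.80
Thyroglobulin	ELSVLLPNR	2	1	1039.64	1039.60	43	0.74	0.78	0.78	1.00
Thyroglobulin	KGQEFTITGQK	3	3	1235.63	1235.65	-15	0.78	0.99	0.74	1.33
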