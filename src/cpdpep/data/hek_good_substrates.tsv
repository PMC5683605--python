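precursor	sequence	z	t	obs_m	theor_m	ppm	r_100nM	r_10nM	r_1nM	r_0.1nM
Eukaryotic translation initiation factor 5A	SAMTEEAAVAIKAMAK	3	3	1620.84	1620.821	11	<0.10	0.98	1.02	0.90
Acidic nuclear phosphoprotein pp32	STIEPLKK	3	3	914.53	914.54	-20	<0.10	1.12	1.15	1.00
40S Ribosomal protein S21	KADGIVSK	3	3	816.45	816.470	-20	<0.10	0.83	0.89	0.96
Histidine triad nucleotide-binding protein 1	Ac-ADEIAKAQVAR	2	1	1212.67	1212.646	21	0.15	1.03	1.03	1.14
Vimentin	AELEQLKGQGKSR	3	3	1442.78	1442.78	0	0.23	0.95	0.97	1.11
Eukaryotic translation initiation factor 5A	SAMoxTEEAAVAIKAMAK	3	3	1636.83	1636.821	3	0.32	0.98	1.00	0.94
Eukaryotic translation initiation factor 5A	NMDVPNIKR	3	2	1085.57	1085.565	4	0.38	0.95	1.05	0.72
Hematological and neurological expressed 1 protein	Ac-TTTTTFKGVDPNSRNSSR	3	1	2010.02	2009.977	20	0.40	1.13	1.07	0.97
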