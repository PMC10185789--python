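# Reference clinical table: 15-participant chronic spinal-cord-injury cohort
# (demographics, pain and spasticity scores) used by worked examples and for
# calibrating the synthetic-cohort defaults. MD = missing data; n.a. = not available.
ID	Age	Gender	AIS	NLI	TSI	SCIPI	CPG	NocP	NRS	MAS	SCAT	distance_FS_FH_m	distance_FD_FH_m
01	53	M	A	C2	32.4	2	N	Y	6	2.67	1.00
02	31	M	A	T8	13.3	0	N	N	0	2.33	1.17
03	36	M	A	T4	14.4	1	N	N	0	4.17	1.33
04	45	F	A	T4	2.7	7	Y	N	5	0.17	0.00
05	62	M	A	T4	6.1	5	Y	N	7	0.33	0.00
06	42	F	A	T7	1.2	7	Y	N	7	0.67	0.67
07	18	F	D	T5	1.1	1	N	Y	1	3.67	0.83
08	59	M	D	C6	1.5	2	N	Y	1	2.17	0.83
09	26	F	C	T3	1.7	4	Y	N	7	4.33	1.17
10	62	F	D	C3	3.8	6	Y	N	7	2.16	0.50	0.42	0.40
11	63	M	D	T5	8.3	3	N	Y	3	MD	1.67
12	61	F	D	T5	1.9	3	Y	N	4	0.00	0.00
13	41	F	D	C5	0.9	5	N	Y	6	MD	0.50
14	46	M	D	C2	2.0	4	Y	N	8	0.83	0.17
15	54	M	D	T1	6.7	5	Y	N	6	0.33	0.16
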