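number	locus	chrom	start	end	LTR5	gag	pro	pol	env	LTR3
1	16p12.3	chr16	19393581	19402152	100.00	99.83	99.89	99.39	99.17	99.66
2	2p12	chr2	82022660	82031279	98.98	99.72	99.89	99.43	99.90	99.15
3	15q21.1	chr15	45234477	45243073	99.83	99.27	100.00	99.66	99.56	99.83
4	8p11.1	chr8	43694016	43702583	99.83	99.44	98.31	99.39	99.66	99.83
5	13q31.1	chr13	84869526	84877320	35.78	99.55	52.20	99.77	99.80	99.32
6	4q33	chr4	170126345	170133883	99.66	99.89	99.77	99.70	13.93	0.00
7	6p12.3	chr6	48873675	48879725	99.15	92.79	65.84	6.13	99.85	99.66
8	Yp11.2	chrY	9273707	9279611	88.42	90.73	63.81	6.36	98.83	99.49
9	8q24.3	chr8	145019974	145032719	90.00	0.00	0.79	99.77	99.90	95.23
10	Yq11.223	chrY	21580120	21585551	88.25	91.74	64.83	6.25	99.36	15.84
11	19q13.2	chr19	40954172	40959178	98.98	98.94	64.26	6.17	67.40	77.51
12	Yp11.2	chrY	8121821	8126768	99.66	76.49	14.09	6.40	99.17	98.81
13	Yp11.2	chrY	8996062	9000755	0.00	80.23	64.37	6.47	99.80	95.55
14	Yq11.222	chrY	18622534	18626952	96.76	75.21	0.00	0.00	84.75	98.47
15	Yq11.223	chrY	21845475	21850069	0.00	70.85	64.60	6.40	99.32	99.15
16	21q21.1	chr21	18563368	18566735	0.00	0.00	95.26	96.12	0.00	0.00
17	5q33.3	chr5	156660448	156663815	0.00	0.00	95.26	96.12	0.00	0.00
18	1q22	chr1	155629408	155632775	0.00	0.00	95.26	96.12	0.00	0.00
19	7q36.1	chr7	150561277	150563994	0.00	0.00	0.00	16.91	99.02	54.51
20	8q21.13	chr8	78652302	78654820	0.00	0.00	0.00	0.00	87.34	100.00
21	10q24.2	chr10	99822511	99825532	0.00	0.00	52.29	95.43	0.00	0.00
22	12q13.11	chr12	48509228	48511681	0.00	0.00	88.72	63.52	0.00	0.00
23	Yq11.222	chrY	17669948	17671523	52.81	62.09	0.00	0.00	0.00	0.00
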