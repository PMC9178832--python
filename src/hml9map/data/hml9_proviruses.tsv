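number	locus	chrom	strand	start	end	length_bp	coverage_pct	range_pct	qgap_pct	indel	context	gene
1	16p12.3	chr16	-	19393581	19402152	8572	96.00	90-100	1.01	NA	Exon_intron	AC130456.2
2	2p12	chr2	+	82022660	82031279	8620	95.91	90-100	1.13	NA	Intergenic	NA
3	15q21.1	chr15	-	45234477	45243073	8597	95.34	90-100	1.85	NA	Exon_intron	AC051619.4
4	8p11.1	chr8	-	43694016	43702583	8568	95.10	90-100	2.14	NA	Intergenic	NA
5	13q31.1	chr13	+	84869526	84877320	7795	86.84	80-90	6.67	NA	Exon_intron	AL445588.1
6	4q33	chr4	-	170126345	170133883	7539	70.03	70-80	0.79	Insertion	Intergenic	NA
7	6p12.3	chr6	+	48873675	48879725	6051	64.84	60-70	34.48	Deletion	Intergenic	NA
8	Yp11.2	chrY	-	9273707	9279611	5905	59.83	50-60	39.23	Deletion	Intergenic	NA
9	8q24.3	chr8	+	145019974	145032719	12746	57.06	50-60	0.79	Insertion	Intergenic	NA
10	Yq11.223	chrY	+	21580120	21585551	5432	57.04	50-60	38.30	Deletion	Exon_intron	TTTY13
11	19q13.2	chr19	+	40954172	40959178	5007	56.66	50-60	41.93	Deletion	Intergenic	NA
12	Yp11.2	chrY	-	8121821	8126768	4948	54.57	50-60	44.92	Deletion	Intergenic	NA
13	Yp11.2	chrY	+	8996062	9000755	4694	50.80	50-60	41.95	Deletion	Intergenic	NA
14	Yq11.222	chrY	-	18622534	18626952	4419	47.33	40-50	52.23	Deletion	Intergenic	NA
15	Yq11.223	chrY	-	21845475	21850069	4595	43.18	40-50	49.78	Deletion/insertion	Exonic_intergenic	AC024236.1
16	21q21.1	chr21	-	18563368	18566735	3368	34.26	30-40	8.19	NA	Exon_intron	MIR548XHG
17	5q33.3	chr5	-	156660448	156663815	3368	34.14	30-40	8.50	NA	Intron	SGCD
18	1q22	chr1	-	155629408	155632775	3368	33.75	30-40	9.56	NA	Intron	AL353807.5
19	7q36.1	chr7	-	150561277	150563994	2718	27.92	20-30	10.27	Deletion	Intergenic	NA
20	8q21.13	chr8	+	78652302	78654820	2519	26.60	20-30	0.30	NA	Intron	AC068700.2
21	10q24.2	chr10	-	99822511	99825532	3022	25.36	20-30	24.65	Deletion/insertion	Intron	ABCC2
22	12q13.11	chr12	+	48509228	48511681	2454	18.44	10-20	33.18	Deletion/insertion	Intergenic	NA
23	Yq11.222	chrY	-	17669948	17671523	1576	17.11	10-20	12.69	Deletion	Intergenic	NA
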