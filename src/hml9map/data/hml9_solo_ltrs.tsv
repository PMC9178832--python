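number	locus	chrom	strand	start	end	length_bp	ltr_pct	coverage_pct	range_pct	qgap_pct	indel	context	gene
1	14q21.1	chr14	+	38011040	38012012	973	101.36	6.91	0-10	35.61	Deletion/insertion	Intron	TTC6
2	Xq21.32	chrX	-	93273183	93274197	1015	100.85	6.88	0-10	2.47	Insertion	Intergenic	NA
3	2q31.1	chr2	+	180236847	180237437	591	100.34	6.84	0-10	0.34	NA	Intergenic	NA
4	18p11.31	chr18	-	4527618	4528209	592	100.17	6.83	0-10	0.00	NA	Intergenic	NA
5	2q11.2	chr2	+	97964920	97965508	589	100.00	6.82	0-10	0.00	NA	Intron	TMEM131
6	15q14	chr15	+	39011033	39011621	589	100.00	6.82	0-10	0.00	NA	Intron	LINC02694
7	2p12	chr2	-	81304430	81305068	639	99.83	6.81	0-10	0.00	NA	Intergenic	NA
8	2q32.3	chr2	-	194256159	194256746	588	99.83	6.81	0-10	0.00	NA	Intergenic	NA
9	3q26.1	chr3	-	163283189	163283777	589	99.83	6.81	0-10	0.00	NA	Intron	LINC01192
10	4q26	chr4	+	116980222	116980809	588	99.83	6.81	0-10	0.34	NA	Intergenic	NA
11	4p15.31	chr4	+	19556097	19556684	588	99.83	6.81	0-10	0.17	NA	Intron	AC024230.1
12	7p21.2	chr7	+	14509240	14509827	588	99.83	6.81	0-10	0.00	NA	Intron	DGKB
13	8q11.21	chr8	-	51178592	51179179	588	99.83	6.81	0-10	0.00	NA	Intergenic	NA
14	11q12.3	chr11	-	62185237	62185824	588	99.83	6.81	0-10	0.00	NA	Intergenic	NA
15	2q21.3	chr2	+	135521883	135522470	588	99.66	6.80	0-10	0.17	NA	Intron	ZRANB3
16	3p12.2	chr3	-	81329902	81330488	587	99.66	6.80	0-10	0.17	NA	Intergenic	NA
17	3p12.1	chr3	-	83618409	83618995	587	99.66	6.80	0-10	0.17	NA	Intergenic	NA
18	5q21.3	chr5	-	105998962	105999549	588	99.66	6.80	0-10	0.34	NA	Intergenic	NA
19	10p12.31	chr10	-	18856645	18857233	589	99.66	6.80	0-10	0.17	NA	Intergenic	NA
20	Yq11.23	chrY	-	25974734	25975320	587	99.66	6.80	0-10	0.17	NA	Intergenic	NA
21	6q14.1	chr6	-	82297755	82298498	744	99.49	6.78	0-10	0.34	Insertion	Intergenic	NA
22	Xp22.2	chrX	+	11033746	11034330	585	99.32	6.77	0-10	0.51	NA	Intron	AC073529.1
23	2p12	chr2	+	77807602	77808185	584	99.15	6.76	0-10	0.68	NA	Intron	AC012494.1
24	1q23.3	chr1	+	162419359	162419942	584	98.98	6.75	0-10	0.17	NA	Intergenic	NA
25	Xq27.2	chrX	-	142767872	142768454	583	98.98	6.75	0-10	0.00	NA	Intergenic	NA
26	2q31.1	chr2	+	171365032	171365617	586	98.64	6.73	0-10	1.19	NA	Intron	METTL8
27	5q13.3	chr5	+	75859521	75860102	582	98.64	6.73	0-10	0.17	NA	Intergenic	NA
28	Xq27.3	chrX	-	144791258	144791846	589	98.47	6.71	0-10	1.37	NA	Intergenic	NA
29	12q12	chr12	+	38144469	38145052	584	98.30	6.70	0-10	1.03	NA	Intergenic	NA
30	15q21.3	chr15	-	54594796	54595373	578	98.13	6.69	0-10	2.04	NA	Intron	UNC13C
31	21q11.2	chr21	-	14080466	14081052	587	97.79	6.67	0-10	2.05	NA	Intron	AP001347.1
32	4q28.2	chr4	+	129080872	129081454	583	97.61	6.66	0-10	2.22	NA	Intron	SCLT1
33	3q25.2	chr3	-	154944330	154944911	582	97.44	6.64	0-10	2.56	NA	Intergenic	NA
34	11q24.2	chr11	+	124270705	124271275	571	96.93	6.61	0-10	0.00	NA	Intergenic	NA
35	2q14.3	chr2	-	125024208	125024792	585	96.76	6.60	0-10	3.07	NA	Intergenic	NA
36	6q27	chr6	+	169084226	169084808	583	96.76	6.60	0-10	3.07	NA	Intergenic	NA
37	13q13.3	chr13	-	38319721	38320300	580	96.76	6.60	0-10	3.24	NA	Intron	LINC00571
38	7q35	chr7	+	143472173	143472744	572	96.08	6.55	0-10	3.75	NA	Intron	EPHA1-AS1
39	14q21.3	chr14	+	48011215	48011780	566	95.91	6.54	0-10	0.53	NA	Intergenic	NA
40	3p21.31	chr3	+	44534488	44535059	572	95.74	6.53	0-10	3.77	NA	Intergenic	NA
41	2q22.1	chr2	-	138860917	138861512	596	95.06	6.48	0-10	3.79	NA	Intergenic	NA
42	12p13.32	chr12	-	4720007	4720593	587	94.89	6.47	0-10	4.95	NA	Intron	AC005833.1
43	3p14.2	chr3	-	59469489	59470030	542	91.82	6.26	0-10	3.23	NA	Intron	AC126121.3
44	1q24.2	chr1	+	168457190	168457732	543	90.80	6.19	0-10	0.37	NA	Intron	AL023755.1
45	20p13	chr20	-	2809052	2809886	835	88.42	6.03	0-10	0.38	Insertion	Intergenic	NA
46	18q21.33	chr18	+	63648105	63648555	451	76.49	5.22	0-10	0.22	NA	Intron	SERPINB11
47	17q22	chr17	+	52961655	52962071	417	70.87	4.83	0-10	0.24	NA	Intergenic	NA
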