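case_id	clinical_diagnosis	group	age_onset	age_death	duration	sex	brain_weight	mutations	pm_delay
1	AD	FTLD-TDP A	64	73	9	M	1252	C9orf72	61.1
2	CBD	FTLD-TDP A	51	61	10	M	1065		35.3
3	FTD	FTLD-TDP A	59	65	6	M	1176	C9orf72	30.0
4	PNFA	FTLD-TDP A	66	72	6	M	1274		68.2
5	FTD	FTLD-TDP A	57	60	3	M	1673		40.4
6	bvFTD	FTLD-TDP A	58	66	8	F	850	C9orf72	107.1
7	Control	FTLD-TDP A	75	79	4	M			10.0
8	FTD	FTLD-TDP A	52	58	6	M	1303	C9orf72	49.8
9	MND	FTLD-TDP A	47	53	6	M	1390		33.7
10	FTD	FTLD-TDP A	53	63	10	M	955	C9orf72	77.3
11	bvFTD	FTLD-TDP A	62	68	6	F		GRN (Q130fs)	99.8
12	MND	FTLD-TDP A	67	69	2	M	1398		62.5
13	CBD	FTLD-TDP A	75	79	4	F	1119		36.3
14	PSP	FTLD-TDP A	83	87	4	F	1226		68.9
15	FTD	FTLD-TDP A	57	62	5	M			92.9
16	bvFTD	FTLD-TDP A	62	72	10	M	1320	TBK1	97.4
17	bvFTD	FTLD-TDP A	57	63	6	F	851		85.3
18	PNFA	FTLD-TDP A	57	62	5	F	981	C9orf72	63.1
19	bvFTD	FTLD-TDP A	53	61	8	M	994	GRN (C31fs)	72.6
20	FTD-MND	FTLD-TDP A	58	67	9	F	1000	GRN + C9orf72	115.0
21	FTD	FTLD-TDP A	62	68	6	M	1371	C9orf72	99.0
22	bvFTD	FTLD-TDP A	43	45	2	M	1015	C9orf72	25.9
23	PNFA	FTLD-TDP A	56	67	11	F	789	C9orf72	85.6
24	FTD	FTLD-TDP A	59	71	12	F	1014	TBK1	76.0
25	bvFTD	FTLD-TDP A	49	55	6	M	974	GRN (C31fs)	29.3
26	FTD-MND	FTLD-TDP A	66	74	8	F	782	C9orf72	85.8
27	FTD	FTLD-TDP A	54	60	6	M	1350	C9orf72	32.3
28	FTD-MND	FTLD-TDP A	66	71	5	M	1431	C9orf72	51.9
29	FTD-MND	FTLD-TDP B	63	67	4	F	1232		45.5
30	MND	FTLD-TDP B	67	69	2	M	1300		70.2
31	FTD	FTLD-TDP B	63	83	20	F	970		45.1
32	FTD	FTLD-TDP C	52	65	13	F	899		27.7
33	bvFTD	FTLD-TDP C	64	66	2	F	1186	C9orf72	94.1
34	SD	FTLD-TDP C	73	83	10	M	1167		59.8
35	SD	FTLD-TDP C	58	72	14	F	972		31.2
36	SD	FTLD-TDP C	67	76	9	M	1086		39.5
37	SD	FTLD-TDP C	58	73	15	F	976		37.9
38	SD	FTLD-TDP C	59	73	14	F	936		83.7
39	SD	FTLD-TDP C	64	78	14	M	1110		26.8
40	SD	FTLD-TDP C	64	74	10	M	1230		19.0
41	SD	FTLD-TDP C	50	65	15	M	1057		51.8
42	FTD	FTLD-TDP C	61	66	5	M	1117		70.8
43	PNFA	FTLD-TDP C	77	80	3	F	1502		26.3
44	IBMPFD	FTLD-TDP D		48		F	1210	VCP	53.5
45	IBMPFD	FTLD-TDP D	53	71	18	M	1363		54.1
46	bvFTD	FTLD-Tau	55	66	11	M	1208	MAPT (R406W)	60.8
47	PSP	FTLD-Tau	54	58	4	M	1225		78.3
48	bvFTD	FTLD-Tau	59	66	7	M	1399	MAPT (10 + 16)	58.2
49	bvFTD	FTLD-Tau	68	74	6	M	1048	MAPT (K280del)	125.0
50	bvFTD	FTLD-Tau	45	51	6	M	1046	MAPT (10 + 16)	52.6
51	ALS	FTLD-FUS	44	46	2	M	1570		96.0
52	ALS	FTLD-FUS	69	72	3	F	1268		93.0
53	CBD	FTLD-Ni	48	54	6	F	1106		106.3
54	bvFTD	FTLD-Ni	50	57	7	M	1444		44.0
55	ALS	ALS	55	59	4	M	875		36.0
56	ALS	ALS	63	66	3	F	1316		66.0
57	ALS	ALS	58	63	5	F	1228	C9orf72	66.5
58	ALS	ALS	40	53	13	F	1226		42.3
59	ALS	ALS	77	80	3	F	1086		5.0
60	ALS	ALS	80	84	4	M	1453		56.3
61	ALS	ALS	74	76	2	M	1138	C9orf72	26.4
62	Control	Control		69		M	1435		171.0
63	Control	Control		67		M	1350		2.5
64	Control	Control		73		F	1214		24.0
65	Control	Control		88		M	1077		16.3
66	Control	Control		79		F	1288		88.8
67	Control	Control		86		F	1234		120.0
68	Control	Control		93		F	1128		29.7
69	Control	Control		83		F	1263		99.0
70	Control	Control		68		F	1330		45.1
71	Control	Control		70		M	1544		53.5
72	Control	Control		92		M	1213		46.3
73	Control	Control		96		F	1032		60.0
74	Control	Control		91		F	1130		71.8
75	Control	Control		84		F			40.6
76	Control	Control		80		M			11.5
77	MSA	Control		83		M	1244		105.5
78	Control	Control		94		F			27.0
79	Control	Control		29		M	1590		44.0
80	Control	Control		25		M	1640		53.0
81	Control	Control		30		M	1670		71.0
82	Control	Control		25		M	1500		81.0
83	Control	Control		28		M	1330		38.0
84	Control	Control		34		M	1530		99.0
85	Control	Control		39		M	1360		76.0
86	Control	Control		37		F	1360		126.0
87	Control	Control		39		M	1470		86.0
88	Control	Control		46		M	1380		76.0
89	Control	Control		46		F	1400		99.0
90	Control	Control		48		M	1480		58.0
91	Control	Control		50		M	1350		122.0
92	Control	Control		57		M	1600		70.0
93	Control	Control		58		M	1650		96.0
94	Control	Control		53		F	1420		107.0
95	Control	Control		57		F	1320		73.0
96	Control	Control		51		M	1460		52.0
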