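peak_no	rt_min	formula	adduct	experimental_mz	calculated_mz_printed	error_ppm_printed	name
1	3.740	C12H22O11	[M-H]-	341.1092	341.1089	-0.77	Sucrose
2	4.329	C7H10O5	[M-H]-	173.0449	173.0455	3.72	Shikimic acid
3	4.623	C4H6O5	[M-H]-	133.0139	133.0142	2.59	Malic acid
4	6.683	C4H6O4	[M-H]-	117.0190	117.0193	2.81	Succinic acid
5	6.983	C6H10O5	[M-H]-	161.0451	161.0455	2.76
6	8.512	C7H6O5	[M-H]-	169.0138	169.0142	2.63	Gallic acid
7	12.384	C15H14O7	[M-H]-	305.0665	305.0667	0.58	Epigallocatechin
8	13.199	C30H26O13	[M-H]-	593.1287	593.1301	2.30	Kaempferol-3-O-b-D-galactoside
9	13.913	C7H6O4	[M-H]-	153.0188	153.0193	3.46	Protocatechuic acid
10	14.320	C30H26O13	[M-H]-	593.1290	593.1301	1.79	Kaempferol-3-O-b-D-glucoside
11	16.358	C8H14O6	[M-H]-	205.0717	205.0718	0.30
12	17.471	C30H26O12	[M-H]-	577.1347	577.1351	0.78	Catechin dimers
13	18.091	C30H26O12	[M-H]-	577.1342	577.1351	1.64	Catechin dimers
14	18.702	C45H38O18	[M-H]-	865.1961	865.1985	2.81	Catechin trimers
15	19.721	C15H14O6	[M-H]-	289.0724	289.0718	-2.20	Catechin
16	20.944	C11H12O6	[M-H]-	239.0560	239.0561	0.47
17	22.778	C30H26O11	[M-H]-	561.1392	561.1402	1.84	Catechin dimers
18	24.204	C15H14O6	[M-H]-	289.0720	289.0718	-0.82	Epicatechin
19	27.669	C21H20O13	[M-H]-	479.0830	479.0831	0.24	Myricetin 3-O-galactoside
20	27.975	C21H20O13	[M-H]-	479.0826	479.0831	1.07	Myricetin 3-O-glucoside
21	28.586	C30H26O11	[M-H]-	561.1389	561.1402	2.38	Catechin dimers
22	30.239	C16H16O7	[M-H]-	319.0829	319.0823	-1.79
23	30.726	C21H20O12	[M-H]-	463.0880	463.0882	0.43	Hyperoside
24	31.134	C21H20O12	[M-H]-	463.0876	463.0882	1.29	Isoquercitrin
25	33.477	C14H12O4	[M-H]-	243.0662	243.0663	0.34	9,10-Dihydro-2,3,5,7-phenanthrenetetraol
26	33.885	C17H14O7	[M-H]-	329.0667	329.0667	-0.07	Caryatin
27	35.210	C14H10O4	[M-H]-	241.0506	241.0506	0.13	2,4,5,6-Phenanthrenetetrol
28	35.923	C19H20O7	[M-H]-	359.1133	359.1136	0.91	Diosbulbin M
29	36.636	C15H10O8	[M-H]-	317.0301	317.0303	0.60	Myricetin
30	37.248	C19H22O7	[M-H]-	361.1286	361.1293	1.87	Diosbulbin L
31	37.553	C17H14O6	[M-H]-	313.0713	313.0718	1.47	3,5-Dimethoxykaempferol
32	37.961	C19H22O7	[M-H]-	361.1286	361.1293	1.87	Diosbulbin C
33	38.267	C18H16O7	[M-H]-	343.0808	343.0823	4.44	3,5,3'-Trimethoxyquercetin
34	38.267	C28H20O8	[M-H]-	483.1069	483.1085	3.39
35	39.039	C19H22O6	[M+COOH]-	391.1412	391.1398	2.64	Diosbulbin G
36	42.139	C15H10O7	[M-H]-	301.0349	301.0354	1.58	Quercetin
37	42.954	C19H20O6	[M-H]-	343.1179	343.1187	2.36	Diosbulbin D
38	43.747	C19H20O6	[M+COOH]-	389.1255	389.1242	-3.80	Diosbulbin B
39	44.493	C21H24O7	[M+Cl]-	423.1234	423.1216	-4.63	8-Epidiosbulbin E acetate
40	47.234	C15H10O6	[M-H]-	285.0407	285.0405	-0.83	Kaempferol
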