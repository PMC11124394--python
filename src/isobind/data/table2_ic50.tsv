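compound	SW480	SW620	PC3	HepG2	MDA	A549	HaCaT
3	>100	>100	>100	>100	>100	>100	>100
4	57.6 ± 9.4	61.8 ± 11.4	65.9 ± 16.1	63.7 ± 12.6	55.2 ± 17.3	53.0 ± 10.8	68.3 ± 19.6
5	73.6 ± 8.4	57.5 ± 3.9	43.2 ± 10.2	42.1 ± 10.2	45.2 ± 5.5	46.6 ± 12.1	45.0 ± 7.2
6	>100	>100	>100	>100	>100	>100	>100
7	>100	>100	>100	>100	>100	>100	>100
8	32.7 ± 6.7	24.2 ± 8.4	31.0 ± 5.5	25.54 ± 6.3	23.1 ± 7.7	19.6 ± 2.0	23.9 ± 3.9
9	>100	>100	>100	>100	>100	>100	>100
10	52.2 ± 17.9	46.0 ± 11.4	44.9 ± 12.1	50.5 ± 10.5	55.5 ± 20.3	49.3 ± 16.3	55.3 ± 17.0
11	50.2 ± 11.2	50.8 ± 14.5	67.2 ± 18.6	50.5 ± 17.5	61.4 ± 21.8	65.1 ± 17.3	58.6 ± 22.2
12	>100	>100	>100	>100	>100	>100	>100
13	59.8 ± 23.0	62.4 ± 3.1	55.8 ± 23.7	56.2 ± 22.2	59.8 ± 18.8	82.1 ± 13.9	68.5 ± 4.8
14	>100	>100	>100	>100	>100	>100	>100
15	>100	>100	>100	>100	>100	>100	>100
16	>100	>100	>100	>100	99.8 ± 3.9	92.8 ± 7.7	>100
17	>100	>100	>100	>100	>100	>100	>100
18	>100	>100	>100	89.6 ± 24.4	66.7 ± 6.4	62.2 ± 8.6	>100
19	>100	>100	>100	>100	>100	>100	>100
20	18.8 ± 0.8	20.9 ± 2.9	23.7 ± 10.3	25.8 ± 9.6	19.0 ± 7.1	19.4 ± 2.2	20.5 ± 9.7
21	>100	>100	>100	>100	>100	>100	>100
22	>100	>100	>100	>100	>100	>100	>100
CA4	0.00281 ± 0.00017	0.00221 ± 0.00088	0.00210 ± 0.00026	0.00158 ± 0.00019	0.00372 ± 0.00027	0.00343 ± 0.00096	0.00427 ± 0.00047
podophyllotoxin	0.0444 ± 0.0022	0.0292 ± 0.0078	0.0129 ± 0.0015	0.0258 ± 0.0056	0.0293 ± 0.0028	0.0247 ± 0.0039	0.0316 ± 0.0040
colchicine	0.166 ± 0.065	0.130 ± 0.089	0.118 ± 0.047	0.107 ± 0.025	0.110 ± 0.015	0.094 ± 0.009	0.104 ± 0.012
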