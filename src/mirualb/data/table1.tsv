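id	group	sex	age	hba1c	duration	cycle	cad	stroke	pvd	neuropathy	retinopathy	htn
1	IMA	F	27.4	10.4	19.2	3	-	-	-	-	-	-
2	PMA	F	22.7	11.8	20.25	3	-	-	-	-	-	-
3	IMA	F	29.9	11.4	18.6	5	-	-	-	-	-	-
4	PMA	F	26.3	13.1	18	5	-	-	-	-	+	-
5	IMA	F	24	10	21.2	2	-	-	-	-	-	-
6	IMA	F	24.3	14.3	19.7	2	-	-	-	-	-	-
7	IMA	F	26.9	10.4	18.5	2	-	-	-	-	-	-
8	PMA	F	25.2	8.2	12.9	2	-	-	-	-	-	-
9	IMA	M	30.66	11	19.97	3	-	-	-	-	+	-
10	PMA	M	23.16	11.5	22.05	3	-	-	+	-	-	-
11	IMA	M	41.7	6.6	30.54	6	-	-	-	-	-	-
12	PMA	M	38.97	5.2	31.54	2	-	-	-	-	+	-
13	IMA	M	39.08	12.4	24.52	6	-	-	-	-	-	-
14	PMA	M	28.35	11.6	27.01	4	-	-	-	-	+	-
15	PMA	M	27.16	13.9	24.3	2	+	-	-	-	+	-
16	IMA	M	23.13	12.1	9.77	2	-	-	-	-	-	-
17	PMA	M	22.8	13	12.9	3	-	-	-	-	-	-
18	N	F	40.32	7.1	29.63	10	-	-	-	+	-	-
19	N	F	48.93	8.3	36.73	10	-	-	-	+	+	-
20	N	F	51.16	8	46.96	10	-	-	+	+	+	-
21	N	F	39.45	7.9	29.77	10	-	-	-	-	-	-
22	N	F	41.19	9.8	38.13	10	+	-	+	+	+	-
23	N	M	48.72	6.6	33.76	10	-	-	-	-	-	-
24	N	M	42.46	9.8	33.4	10	+	-	-	-	-	+
25	N	M	42.5	8.2	36	10	-	-	-	-	-	-
26	N	M	35.35	9.1	28.53	10	+	-	-	+	+	-
27	N	M	38.54	7.7	27.81	10	-	-	-	-	-	-
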