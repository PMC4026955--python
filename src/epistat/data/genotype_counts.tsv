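locus	variant	g0	g1	g2	controls_g0	controls_g1	controls_g2	asthma_g0	asthma_g1	asthma_g2	allergic_g0	allergic_g1	allergic_g2	nonallergic_g0	nonallergic_g1	nonallergic_g2
GPX2	G>A	GG	GA	AA	210	4	0	207	8	0	152	4	0	52	4	0
GPX3	G>A	GG	GA	AA	105	91	18	113	86	16	83	63	10	28	22	6
GPX4	C718T	TT	TC	CC	31	110	73	33	102	80	25	77	54	8	23	25
GSR	T>C	TT	TC	CC	40	109	65	32	107	76	17	79	60	15	25	16
SOD2	A16V	AA	AV	VV	59	108	47	49	111	55	34	82	40	15	27	14
SOD3	A40T	AA	AT	TT	21	96	97	24	90	101	19	63	74	4	25	27
PRDX1	C>A	CC	CA	AA	182	31	1	188	27	0	138	18	0	47	9	0
TXNRD1	C>G	CC	CG	GG	140	66	8	145	63	7	101	50	5	42	12	2
FMO3	E158K	EE	EK	KK	57	121	36	59	113	43	39	87	30	20	24	12
TNF	-308G>A	GG	GA	AA	170	40	4	162	51	2	118	37	1	42	13	1
IL1B	-511C>T	CC	CT	TT	114	76	24	91	105	20	67	75	14	23	27	6
IL3_S27P	S27P	SS	SP	PP	120	76	18	104	88	24	77	60	19	25	27	4
IL3_-15C>T	-15C>T	CC	CT	TT	120	77	17	103	89	24	77	60	19	25	27	4
IL5	C-703T	CC	CT	TT	90	108	16	132	72	12	97	52	7	31	20	5
CSF2RB	G1972A	GG	GA	AA	136	62	3	160	54	2	118	36	2	39	17	0
IL9	T113M	TT	TM	MM	146	59	9	159	55	2	113	41	2	44	12	0
IL13	-1111C>T	CC	CT	TT	114	84	16	101	96	18	75	66	15	26	28	2
SCGB1A1	A38G	AA	AG	GG	25	97	90	28	102	85	23	70	63	5	31	20
SERPINA1_E288V	E288V	EE	EV	VV	211	3	0	212	4	0	153	3	0	55	1	0
SERPINA1_D365N	D365N	DD	DN	NN	210	4	0	214	2	0	153	3	0	55	1	0
SERPINA1_1331G>A	1331G>A	GG	GA	AA	188	25	1	187	29	0	133	23	0	50	6	0
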