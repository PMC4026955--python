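subtype	sex	combo	case_n	case_total	control_n	control_total	chi2	or	ci_low	ci_high	ci_low_tol	ci_high_tol
allergic	M	GPX1 198PL x GPX2 GG	34	64	38	105	4.66	2.00	1.06	3.76		
allergic	M	GPX1 198PL x GSR TC	20	64	19	105	3.88	2.06	1.00	4.25		
allergic	M	GPX1 198PL x CAT -21AA	7	64	2	105	4.77	5.40	1.25	23.42		
allergic	M	GPX1 198PL x GCLM -588CT	12	64	6	105	5.80	3.64	1.33	9.96		
allergic	M	GPX1 198PL x IL5 -703CC	18	64	13	105	6.58	2.77	1.25	6.14		
allergic	M	GPX2 GG x CAT -21AA	12	64	7	105	4.67	3.13	1.19	8.21		
allergic	M	GPX2 GG x IL5 -703CC	38	64	44	105	4.86	2.03	1.08	3.81		
allergic	M	GSR CC x IL5 -703CC	17	64	11	105	7.44	3.09	1.34	7.13		
allergic	M	CAT -21AA x IL5 -703CC	9	64	3	105	5.97	5.01	1.41	17.8		
allergic	M	CAT -21AT x IL5 -703CT	6	64	28	105	6.36	0.30	0.12	0.76		
allergic	F	NQO1 187PP x IL5 -703CC	43	92	33	109	5.75	2.02	1.13	3.60		
allergic	F	NQO1 187PP x IL5 -703CT	18	92	39	109	6.46	0.44	0.23	0.83		
allergic	F	EPHX1 113YY x IL5 -703CT	9	92	24	109	4.59	0.40	0.18	0.89		
allergic	F	GPX1 198PL x GPX4 718TT	11	92	4	109	3.83	3.31	1.07	10.22		
allergic	F	GPX1 198PP x CYBA 640AG	13	92	31	109	5.97	0.41	0.20	0.85		
allergic	F	GPX4 718TC x CYBA 640AG	18	92	43	109	9.33	0.37	0.20	0.71		
nonallergic	M	GPX1 198PL x CAT -21AA	6	29	2	105	11.13	11.45	2.49	52.66		
nonallergic	M	GPX1 198LL x GCLM -588CT	4	29	3	105	3.50	5.17	1.20	22.31		
nonallergic	M	GPX3 GA x FMO3 158KK	5	29	4	105	4.58	5.06	1.37	18.99	0.03	
nonallergic	M	GPX3 GA x GSR TT	6	29	5	105	5.68	5.05	1.49	17.14		
nonallergic	M	GPX3 GA x CAT -21AA	5	29	4	105	4.58	5.06	1.35	18.99		
nonallergic	M	GPX3 GG x GCLM -588CT	11	29	15	105	8.12	3.67	1.47	9.28	0.03	
nonallergic	M	GSR TT x GCLM -588CT	8	29	3	105	15.31	11.58	3.07	43.72		
nonallergic	M	GSR TT x FMO3 158KK	4	29	1	105	7.16	12.29	1.84	82.03		
nonallergic	M	CAT -21AA x CYBA -930GG	5	29	1	105	10.55	15.64	2.44	100.3		
nonallergic	M	CAT -21AA x FMO3 158EE	4	29	1	105	7.16	12.29	1.84	82.03		
nonallergic	M	GCLM -588CT x CYBA -930GG	12	29	10	105	16.8	6.71	2.5	17.96		
nonallergic	M	CYBA -930GG x FMO3 158EE	7	29	5	105	8.22	6.09	1.85	20.05		
nonallergic	F	GPX1 198PL x GPX2 GA	2	27	0	109	3.88	21.47	1.00	461.1		
nonallergic	F	GPX2 GG x IL5 -703CT	6	27	56	109	6.29	0.29	0.11	0.74		
nonallergic	F	GPX2 GA x IL5 -703CC	2	27	0	109	3.88	21.5	1.00	461.2		0.2
nonallergic	F	EPHX1 113YH x IL5 -703CT	1	27	24	109	3.69	0.20	0.04	1.09		
nonallergic	F	EPHX1 113HH x IL5 -703CC	7	27	4	109	11.58	8.58	2.43	30.26		
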