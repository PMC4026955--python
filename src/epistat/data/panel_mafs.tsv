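locus	maf
GPX2	0.009
GPX3	0.297
GPX4	0.402
GSR	0.442
SOD2	0.472
SOD3	0.322
PRDX1	0.077
TXNRD1	0.192
FMO3	0.451
TNF	0.112
IL1B	0.290
IL3_S27P	0.262
IL3_-15C>T	0.259
IL5	0.327
CSF2RB	0.169
IL9	0.180
IL13	0.271
SCGB1A1	0.347
SERPINA1_E288V	0.007
SERPINA1_D365N	0.009
SERPINA1_1331G>A	0.063
SNP22	0.009
SNP23	0.297
SNP24	0.402
SNP25	0.442
SNP26	0.472
SNP27	0.322
SNP28	0.077
SNP29	0.192
SNP30	0.451
SNP31	0.112
SNP32	0.290
SNP33	0.262
SNP34	0.259
SNP35	0.327
SNP36	0.169
SNP37	0.180
SNP38	0.271
SNP39	0.347
SNP40	0.007
SNP41	0.009
SNP42	0.063
SNP43	0.009
SNP44	0.297
SNP45	0.402
SNP46	0.442
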