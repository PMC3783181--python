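# SYNTHETIC example data: growth-rate-like tRNA concentrations (opaque units).
isoacceptor	mu2.5	mu1.6	mu1.07	mu0.7	mu0.4
Ala1B	90.18	77.82	60.51	51.64	45.59
Ala2	49.28	41.19	33.12	27.88	23.87
Arg2	311.64	267.35	203.84	179.08	150.27
Arg3	40.69	33.56	28.71	23.7	20.56
Arg4	276.9	230.09	189.93	159.05	136.42
Arg5	88.07	72.7	61.73	50.64	44.58
Asn	271.43	227.51	185.13	154.61	138.52
Asp1	42.26	37.05	29.81	24.24	21.88
Cys	86.28	74.79	56.8	49.33	41.71
Gln1	35.12	29.67	24.16	19.72	17.87
Gln2	55.78	46.33	36.87	33.06	27.48
Glu2	92.34	77.31	61.69	54.05	47.47
Gly1	108.98	92.96	75.96	61.95	56.42
Gly2	82.55	68.66	54.19	47.39	41.43
Gly3	48.14	42.18	33.14	28.66	23.17
His	119.52	99.27	82.23	68.45	57.46
Ile1	113.36	95.93	77.73	67.32	55.95
Ile2	161.25	135.95	105.6	96.91	82.45
Leu1	82.83	73.05	57.23	48.03	42.61
Leu2	46.82	39.96	31.56	28.18	23.91
Leu3	159.03	133.25	109.69	89.92	82.03
Leu4	114.04	94.83	78.15	66.54	58.7
Leu5	251.37	221.22	175.23	145.7	125.54
Lys	136.67	114.49	92.64	81.35	69.54
Metm	68.79	59.48	45.13	40.14	33.29
Phe	135.47	115.26	94.44	77.49	67.03
Pro1	81.13	66.96	53.29	48.79	41.52
Pro2	155.75	137.41	105.74	86.76	78.97
Pro3	69.63	59.77	48.59	41.47	33.89
Ser1	69.23	59.47	46.43	40.9	34.02
Ser2	54.84	45.71	36.94	32.58	27.0
Ser3	136.41	114.59	91.56	76.79	70.25
Ser5	99.27	87.17	65.62	57.63	48.5
Thr1	65.74	57.95	44.34	39.37	32.78
Thr2	118.88	103.06	83.44	71.07	57.96
Thr3	203.61	169.12	133.98	115.5	102.76
Thr4	119.68	99.52	82.1	68.15	61.81
Trp	263.51	220.55	182.58	157.59	129.34
Tyr1	214.92	180.03	145.79	122.64	106.37
Tyr2	104.51	89.63	73.05	59.46	54.23
Val1	64.26	53.4	44.64	36.69	30.86
Val2A	54.21	44.99	36.52	31.96	26.37
Val2B	424.64	360.31	281.07	242.65	215.35
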