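# SYNTHETIC example data: reference concentrations repeated per time point.
isoacceptor	t0	t2	t7	t17	t32
Ala1B	90.18	90.18	90.18	90.18	90.18
Ala2	49.28	49.28	49.28	49.28	49.28
Arg2	311.64	311.64	311.64	311.64	311.64
Arg3	40.69	40.69	40.69	40.69	40.69
Arg4	276.9	276.9	276.9	276.9	276.9
Arg5	88.07	88.07	88.07	88.07	88.07
Asn	271.43	271.43	271.43	271.43	271.43
Asp1	42.26	42.26	42.26	42.26	42.26
Cys	86.28	86.28	86.28	86.28	86.28
Gln1	35.12	35.12	35.12	35.12	35.12
Gln2	55.78	55.78	55.78	55.78	55.78
Glu2	92.34	92.34	92.34	92.34	92.34
Gly1	108.98	108.98	108.98	108.98	108.98
Gly2	82.55	82.55	82.55	82.55	82.55
Gly3	48.14	48.14	48.14	48.14	48.14
His	119.52	119.52	119.52	119.52	119.52
Ile1	113.36	113.36	113.36	113.36	113.36
Ile2	161.25	161.25	161.25	161.25	161.25
Leu1	82.83	82.83	82.83	82.83	82.83
Leu2	46.82	46.82	46.82	46.82	46.82
Leu3	159.03	159.03	159.03	159.03	159.03
Leu4	114.04	114.04	114.04	114.04	114.04
Leu5	251.37	251.37	251.37	251.37	251.37
Lys	136.67	136.67	136.67	136.67	136.67
Metm	68.79	68.79	68.79	68.79	68.79
Phe	135.47	135.47	135.47	135.47	135.47
Pro1	81.13	81.13	81.13	81.13	81.13
Pro2	155.75	155.75	155.75	155.75	155.75
Pro3	69.63	69.63	69.63	69.63	69.63
Ser1	69.23	69.23	69.23	69.23	69.23
Ser2	54.84	54.84	54.84	54.84	54.84
Ser3	136.41	136.41	136.41	136.41	136.41
Ser5	99.27	99.27	99.27	99.27	99.27
Thr1	65.74	65.74	65.74	65.74	65.74
Thr2	118.88	118.88	118.88	118.88	118.88
Thr3	203.61	203.61	203.61	203.61	203.61
Thr4	119.68	119.68	119.68	119.68	119.68
Trp	263.51	263.51	263.51	263.51	263.51
Tyr1	214.92	214.92	214.92	214.92	214.92
Tyr2	104.51	104.51	104.51	104.51	104.51
Val1	64.26	64.26	64.26	64.26	64.26
Val2A	54.21	54.21	54.21	54.21	54.21
Val2B	424.64	424.64	424.64	424.64	424.64
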