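# SYNTHETIC example relative-adaptiveness weights (not from real expression data).
codon	weight
AAA	1.0
AAC	1.0
AAG	0.707
AAU	0.829
ACA	1.0
ACC	0.746
ACG	0.094
ACU	0.635
AGA	0.633
AGC	0.821
AGG	0.573
AGU	0.742
AUA	1.0
AUC	0.128
AUG	1.0
AUU	0.432
CAA	1.0
CAC	0.453
CAG	0.129
CAU	1.0
CCA	0.612
CCC	0.689
CCG	1.0
CCU	0.714
CGA	0.101
CGC	1.0
CGG	0.786
CGU	0.6
CUA	0.373
CUC	0.651
CUG	1.0
CUU	0.715
GAA	1.0
GAC	1.0
GAG	0.43
GAU	0.208
GCA	0.254
GCC	0.231
GCG	1.0
GCU	0.697
GGA	0.77
GGC	1.0
GGG	0.628
GGU	0.793
GUA	0.091
GUC	1.0
GUG	0.214
GUU	0.199
UAC	0.355
UAU	1.0
UCA	0.108
UCC	0.576
UCG	0.631
UCU	1.0
UGC	1.0
UGG	1.0
UGU	0.619
UUA	0.195
UUC	1.0
UUG	0.136
UUU	0.677
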