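# E. coli K-12 elongator tRNA isoacceptors (editable; initiator Met excluded).
name	amino_acid	anticodon	modification
Ala1B	A	UGC	none
Ala2	A	GGC	none
Arg2	R	ACG	none
Arg3	R	CCG	none
Arg4	R	UCU	none
Arg5	R	CCU	none
Asn	N	GUU	none
Asp1	D	GUC	none
Cys	C	GCA	none
Gln1	Q	UUG	none
Gln2	Q	CUG	none
Glu2	E	UUC	none
Gly1	G	CCC	none
Gly2	G	UCC	none
Gly3	G	GCC	none
His	H	GUG	none
Ile1	I	GAU	none
Ile2	I	CAU	lysidine
Leu1	L	CAG	none
Leu2	L	GAG	none
Leu3	L	UAG	none
Leu4	L	CAA	none
Leu5	L	UAA	none
Lys	K	UUU	none
Metm	M	CAU	none
Phe	F	GAA	none
Pro1	P	CGG	none
Pro2	P	GGG	none
Pro3	P	UGG	none
Ser1	S	UGA	none
Ser2	S	CGA	none
Ser3	S	GCU	none
Ser5	S	GGA	none
Thr1	T	GGU	none
Thr2	T	CGU	none
Thr3	T	GGU	none
Thr4	T	UGU	none
Trp	W	CCA	none
Tyr1	Y	GUA	none
Tyr2	Y	GUA	none
Val1	V	UAC	none
Val2A	V	GAC	none
Val2B	V	GAC	none
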