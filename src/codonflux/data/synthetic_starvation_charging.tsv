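# SYNTHETIC example data: charged fractions over a starvation time course.
isoacceptor	t0	t2	t7	t17	t32
Ala1B	0.908	0.852	0.903	0.519	0.981
Ala2	0.934	0.948	0.944	0.672	0.875
Arg2	0.801	0.987	0.888	0.627	0.978
Arg3	0.935	0.867	0.984	0.597	0.905
Arg4	0.877	0.991	0.978	0.705	0.852
Arg5	0.81	0.998	0.878	0.617	0.96
Asn	0.834	0.975	0.976	0.552	0.874
Asp1	0.866	0.921	0.973	0.519	0.946
Cys	0.834	0.874	0.996	0.539	0.94
Gln1	0.819	0.912	0.998	0.561	0.969
Gln2	0.861	0.997	0.859	0.529	0.952
Glu2	0.911	0.88	0.876	0.742	0.918
Gly1	0.803	0.96	0.901	0.618	0.952
Gly2	0.86	0.901	0.951	0.636	0.935
Gly3	0.943	0.868	0.968	0.642	0.872
His	0.902	0.894	0.888	0.623	0.991
Ile1	0.938	0.872	0.92	0.617	0.862
Ile2	0.872	0.938	0.924	0.731	0.889
Leu1	0.944	0.7	0.6	0.5	0.65
Leu2	0.891	0.08	0.05	0.04	0.05
Leu3	0.814	0.08	0.05	0.04	0.05
Leu4	0.863	0.7	0.6	0.5	0.65
Leu5	0.943	0.7	0.6	0.5	0.65
Lys	0.862	0.927	0.898	0.731	0.922
Metm	0.805	0.999	0.858	0.63	0.872
Phe	0.851	0.959	0.977	0.746	0.87
Pro1	0.901	0.889	0.979	0.663	0.93
Pro2	0.869	0.963	0.969	0.734	0.929
Pro3	0.929	0.94	0.923	0.697	0.989
Ser1	0.829	0.981	0.98	0.51	0.869
Ser2	0.913	0.984	0.932	0.748	0.951
Ser3	0.861	0.873	0.913	0.643	0.934
Ser5	0.939	0.918	0.971	0.533	0.92
Thr1	0.941	0.877	0.948	0.502	0.943
Thr2	0.847	0.919	0.995	0.747	0.878
Thr3	0.948	0.893	0.938	0.61	0.964
Thr4	0.924	0.912	0.887	0.607	0.903
Trp	0.841	0.85	0.868	0.557	0.968
Tyr1	0.899	0.981	0.883	0.552	0.851
Tyr2	0.843	0.983	0.868	0.591	0.85
Val1	0.847	0.851	0.904	0.73	0.988
Val2A	0.862	0.874	0.874	0.691	0.927
Val2B	0.805	0.98	1.0	0.63	0.953
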