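pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	0.735	0.280	-1.988	-1.121	0.449	1.350	0.707	0.504	-0.133	-0.819	-0.307	-0.381	0.806	0.139	2.622	1.816	-0.034	-0.123	1.462	1.773
2	0.285	-2.100	2.149	-0.832	0.286	-0.418	-0.343	1.559	-1.668	-0.431	-0.297	-0.361	-1.510	1.338	0.733	-0.046	0.201	0.349	-0.391	-0.955
3	0.138	1.986	-0.891	-0.718	-0.889	-0.455	0.834	-0.593	-0.463	0.386	-1.340	-0.901	0.608	0.843	0.158	-0.788	0.439	1.056	-1.696	0.890
4	1.720	-1.554	0.949	0.471	1.256	0.174	0.338	0.924	-0.297	0.728	1.197	0.741	-0.028	-0.108	1.636	-0.533	-0.400	1.963	-0.641	-0.499
5	-0.145	-0.946	-1.127	-0.618	1.066	0.859	-1.030	0.483	-0.791	-0.179	0.865	0.516	0.870	0.521	-1.260	-0.024	2.424	-0.490	-0.367	1.000
6	2.242	-0.252	0.477	1.499	-0.305	-1.666	2.658	0.360	-0.124	-0.516	-0.088	-0.722	0.230	0.480	-0.172	-0.267	1.460	0.109	-0.023	0.079
7	0.819	2.211	0.836	1.304	-0.928	-0.200	-1.026	-0.916	0.707	-0.322	0.285	-1.108	0.295	-0.405	2.122	2.016	0.546	0.324	-0.777	0.725
8	-0.552	-0.303	0.468	1.139	-0.719	-1.998	-0.917	-0.179	-0.657	3.238	-1.877	0.432	-1.280	0.324	0.912	1.076	0.962	0.886	-0.267	-0.442
9	0.494	-0.388	-0.888	-0.429	-0.914	1.323	1.716	-0.197	-0.189	-0.367	0.378	0.249	1.636	1.551	0.952	-0.277	-0.383	-0.616	-0.302	-0.503
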