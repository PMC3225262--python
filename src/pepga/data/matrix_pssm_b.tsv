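pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	0.895	0.566	0.743	0.702	0.079	0.981	0.754	0.573	0.843	0.072	0.113	0.968	0.347	0.221	0.136	0.663	0.875	0.782	0.828	0.303
2	0.033	0.526	0.088	0.903	0.945	0.496	0.457	0.970	0.115	0.826	0.647	0.457	0.038	0.643	0.407	0.328	0.019	0.614	0.583	0.489
3	0.832	0.972	0.721	0.282	0.533	0.014	0.191	0.555	0.868	0.311	0.379	0.446	0.714	0.079	0.604	0.485	0.726	0.542	0.836	0.278
4	0.096	0.407	0.083	0.244	0.606	0.330	0.719	0.939	0.258	0.177	0.332	0.809	0.790	0.451	0.560	0.236	0.748	0.987	0.727	0.013
5	0.741	0.704	0.861	0.120	0.971	0.866	0.863	0.326	0.738	0.713	0.225	0.822	0.629	0.786	0.928	0.878	0.064	0.050	0.594	0.850
6	0.746	0.014	0.050	0.430	0.026	0.569	0.198	0.726	0.422	0.795	0.988	0.101	0.346	0.868	0.446	0.023	0.505	0.680	0.846	0.762
7	0.676	0.700	0.165	0.327	0.298	0.078	0.633	0.734	0.564	0.589	0.514	0.023	0.291	0.129	0.669	0.401	0.752	0.961	0.120	0.365
8	0.825	0.269	0.561	0.376	0.850	0.461	0.008	0.731	0.961	0.358	0.196	0.422	0.270	0.209	0.058	0.378	0.465	0.282	0.767	0.825
9	0.903	0.119	0.570	0.023	0.657	0.527	0.063	0.544	0.251	0.006	0.992	0.088	0.366	0.273	0.284	0.037	0.323	0.031	0.841	0.499
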