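pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	8.12	1.85	3.75	8.91	0.41	4.08	4.10	6.07	8.15	9.02	5.80	3.47	8.26	9.86	5.54	0.16	9.96	1.15	8.28	1.63
2	3.93	9.68	9.53	1.45	5.39	7.71	5.72	6.79	4.95	2.06	2.64	7.73	1.74	9.88	2.74	2.95	3.71	2.65	8.10	1.40
3	5.61	7.26	8.57	1.82	7.58	3.89	3.44	0.86	3.61	4.79	5.88	3.54	7.20	9.78	7.59	0.81	2.43	6.82	3.57	2.59
4	6.39	5.20	5.18	6.41	3.78	2.36	4.94	1.05	1.38	3.31	7.62	8.86	8.82	8.63	1.20	9.99	4.15	6.99	6.89	4.98
5	8.73	0.06	2.79	5.85	9.20	7.97	3.02	0.80	6.29	4.04	3.04	3.74	5.79	4.66	0.01	0.61	1.34	1.57	7.17	7.03
6	1.69	8.78	6.13	8.01	4.23	3.18	5.56	9.67	0.23	8.21	5.93	8.46	7.30	7.23	4.72	8.78	3.68	3.66	6.93	8.12
7	2.86	6.24	5.69	2.66	7.12	6.91	6.54	7.81	7.32	3.88	3.04	8.84	3.92	0.25	3.56	6.22	6.71	3.69	9.67	1.71
8	9.52	1.28	0.48	1.19	5.18	4.46	0.54	8.46	4.92	2.45	3.36	6.96	6.12	1.26	0.63	7.12	1.26	7.83	0.82	0.53
9	5.23	2.36	5.43	9.90	2.65	8.49	9.23	4.81	2.47	0.88	2.95	0.93	6.80	2.49	3.76	8.49	3.25	8.67	2.27	0.28
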