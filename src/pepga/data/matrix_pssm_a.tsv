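pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	4	0	2	1	3	2	3	4	2	4	4	1	1	3	1	4	1	3	4	2
2	3	0	1	4	2	4	1	3	0	3	0	1	0	4	3	4	3	1	2	4
3	1	2	1	4	2	4	4	1	0	0	0	3	2	3	0	2	4	4	0	4
4	2	0	0	3	0	2	0	0	0	2	2	3	4	2	0	4	3	4	4	0
5	1	1	1	2	1	4	3	0	0	2	3	0	4	3	2	1	2	0	4	4
6	3	3	3	3	2	1	0	3	4	4	4	3	3	2	0	4	2	2	3	1
7	3	3	2	2	2	1	1	0	3	2	4	4	0	2	0	0	1	4	1	0
8	4	3	4	1	3	0	0	4	3	2	0	3	4	2	0	0	1	3	2	3
9	2	4	4	4	1	0	2	3	1	2	3	0	1	2	0	1	2	4	3	1
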