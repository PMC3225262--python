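pos	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
1	728.9	3832.1	1994.1	632.8	3490.7	5100.2	3175.7	2430.2	3275.5	4954.1	3906.1	5333.7	5209.7	2146.9	5378.0	5274.7	3918.5	4328.0	1913.0	3047.5
2	1580.1	2064.1	598.1	621.7	2490.9	2809.2	1433.9	1641.9	2016.4	1114.7	2743.4	2448.7	1053.1	3648.0	4721.8	674.4	4052.2	2764.6	2064.9	4310.9
3	645.7	1837.2	3739.0	864.8	4399.1	3188.2	2898.5	3496.0	2571.5	3750.5	309.2	3818.4	5459.1	3515.2	5143.4	2433.0	999.0	4661.7	4278.6	3727.4
4	679.6	1960.4	2152.0	5454.5	961.0	3460.0	4693.8	1986.8	3851.0	2130.6	5246.0	5078.7	2654.3	2558.9	232.9	5396.5	1255.2	4159.3	2512.9	1651.5
5	787.7	3601.5	4396.6	4134.9	3147.2	365.6	2657.9	3757.6	2887.6	1866.1	5366.8	4964.2	3807.7	1144.0	5483.3	2962.3	4945.2	3943.0	4701.4	4144.4
6	5430.3	1759.7	1567.9	673.8	1551.1	2302.6	4409.3	4400.5	3329.0	5060.8	497.7	5471.2	5375.4	3100.3	167.0	525.1	3677.0	1849.5	4335.9	4858.9
7	3074.1	4913.0	5549.3	305.1	1534.6	2679.4	2696.2	1828.4	1434.1	2645.5	759.7	2065.9	5429.4	2777.1	5466.7	3636.3	3756.5	5432.0	1019.6	2893.9
8	3383.9	359.8	1270.8	2457.9	1859.7	5316.2	699.5	473.1	1973.5	3823.0	2798.2	4445.9	1102.3	5477.4	1171.7	2176.4	5346.5	44.2	2314.6	1867.1
9	1538.3	2677.6	3634.2	603.1	3535.0	3579.7	5436.2	1200.6	1980.8	2958.4	5422.8	2433.1	918.3	3204.9	3429.5	1200.5	4479.3	475.4	4807.6	3564.9
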