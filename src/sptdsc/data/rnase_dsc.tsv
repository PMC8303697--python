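label	denaturant	denaturant_M	sugar	sugar_M	td_C	dh_kJ_mol	cu	dg25_kJ_mol
water					63.4	448	1.0	36
1 M fructose			fructose	1.0	65.7	442	1.0	37
1 M glucose			glucose	1.0	66.2	443	0.96	37
1 M sucrose			sucrose	1.0	67.6	472	0.98	41
1 M trehalose			trehalose	1.0	68.4	446	1.0	38
1 M urea	urea	1.0			59.7	440	1.0	33
1 M urea + 1 M fructose	urea	1.0	fructose	1.0	62.9	372	0.95	28
1 M urea + 1 M glucose	urea	1.0	glucose	1.0	63.5	432	0.98	35
1 M urea + 1 M sucrose	urea	1.0	sucrose	1.0	64.6	428	0.96	35
1 M urea + 1 M trehalose	urea	1.0	trehalose	1.0	65.6	422	0.99	34
1 M TMU	TMU	1.0			53.9	427	1.0	29
1 M TMU + 1 M fructose	TMU	1.0	fructose	1.0	54.4	344	0.96	22
1 M TMU + 1 M glucose	TMU	1.0	glucose	1.0	55.6	433	0.95	31
1 M TMU + 1 M sucrose	TMU	1.0	sucrose	1.0	56.3	444	1.0	32
1 M TMU + 1 M trehalose	TMU	1.0	trehalose	1.0	56.8	444	1.0	33
1 M NaClO4	NaClO4	1.0			53.0	403	0.96	27
1 M NaClO4 + 1 M fructose	NaClO4	1.0	fructose	1.0	52.6	326	0.97	20
1 M NaClO4 + 1 M glucose	NaClO4	1.0	glucose	1.0	54.5	400	0.95	27
1 M NaClO4 + 1 M sucrose	NaClO4	1.0	sucrose	1.0	55.4	420	0.96	30
1 M NaClO4 + 1 M trehalose	NaClO4	1.0	trehalose	1.0	58.2	392	0.98	28
1 M GdmCl	GdmCl	1.0			53.9	383	0.94	25
1 M GdmCl + 1 M fructose	GdmCl	1.0	fructose	1.0	57.6	391	0.99	28
1 M GdmCl + 1 M glucose	GdmCl	1.0	glucose	1.0	57.4	394	0.95	28
1 M GdmCl + 1 M sucrose	GdmCl	1.0	sucrose	1.0	58.6	392	0.94	28
1 M GdmCl + 1 M trehalose	GdmCl	1.0	trehalose	1.0	61.1	382	0.96	28
0.5 M GdmSCN	GdmSCN	0.5			47.9	320	0.94	17
0.5 M GdmSCN + 1 M fructose	GdmSCN	0.5	fructose	1.0	50.3	320	0.97	19
0.5 M GdmSCN + 1 M glucose	GdmSCN	0.5	glucose	1.0	50.0	324	0.93	19
0.5 M GdmSCN + 1 M sucrose	GdmSCN	0.5	sucrose	1.0	51.0	343	0.94	21
0.5 M GdmSCN + 1 M trehalose	GdmSCN	0.5	trehalose	1.0	53.6	340	0.97	22
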