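label	density_g_L	cosolutes
water	997
1 M fructose	1066	fructose:1.0
1 M glucose	1062	glucose:1.0
1 M sucrose	1126	sucrose:1.0
1 M trehalose	1130	trehalose:1.0
1 M urea	1013	urea:1.0
1 M urea + 1 M fructose	1082	urea:1.0;fructose:1.0
1 M urea + 1 M glucose	1080	urea:1.0;glucose:1.0
1 M urea + 1 M sucrose	1143	urea:1.0;sucrose:1.0
1 M urea + 1 M trehalose	1144	urea:1.0;trehalose:1.0
1 M TMU	999	TMU:1.0
1 M TMU + 1 M fructose	1067	TMU:1.0;fructose:1.0
1 M TMU + 1 M glucose	1068	TMU:1.0;glucose:1.0
1 M TMU + 1 M sucrose	1127	TMU:1.0;sucrose:1.0
1 M TMU + 1 M trehalose	1131	TMU:1.0;trehalose:1.0
1 M NaClO4	1068	NaClO4:1.0
1 M NaClO4 + 1 M fructose	1144	NaClO4:1.0;fructose:1.0
1 M NaClO4 + 1 M glucose	1136	NaClO4:1.0;glucose:1.0
1 M NaClO4 + 1 M sucrose	1198	NaClO4:1.0;sucrose:1.0
1 M NaClO4 + 1 M trehalose	1216	NaClO4:1.0;trehalose:1.0
1 M GdmCl	1022	GdmCl:1.0
1 M GdmCl + 1 M fructose	1090	GdmCl:1.0;fructose:1.0
1 M GdmCl + 1 M glucose	1091	GdmCl:1.0;glucose:1.0
1 M GdmCl + 1 M sucrose	1150	GdmCl:1.0;sucrose:1.0
1 M GdmCl + 1 M trehalose	1156	GdmCl:1.0;trehalose:1.0
0.5 M GdmSCN	1011	GdmSCN:0.5
0.5 M GdmSCN + 1 M fructose	1079	GdmSCN:0.5;fructose:1.0
0.5 M GdmSCN + 1 M glucose	1079	GdmSCN:0.5;glucose:1.0
0.5 M GdmSCN + 1 M sucrose	1145	GdmSCN:0.5;sucrose:1.0
0.5 M GdmSCN + 1 M trehalose	1141	GdmSCN:0.5;trehalose:1.0
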