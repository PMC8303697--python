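"""Published reference values the reproduction tests assert against.

TABLE1: label -> (density g/L, water molarity M, volume packing density xi3)
TABLE3: label -> (dGc_N, dGc_D, ddGc, ddGc_prime) in kJ/mol (prime None for water)
"""

TABLE1 = {
    "water": (997, 55.3, 0.383),
    "1 M fructose": (1066, 49.2, 0.423),
    "1 M glucose": (1062, 48.9, 0.429),
    "1 M sucrose": (1126, 43.5, 0.469),
    "1 M trehalose": (1130, 43.7, 0.483),
    "1 M urea": (1013, 52.9, 0.398),
    "1 M urea + 1 M fructose": (1082, 46.7, 0.437),
    "1 M urea + 1 M glucose": (1080, 46.6, 0.445),
    "1 M urea + 1 M sucrose": (1143, 41.1, 0.484),
    "1 M urea + 1 M trehalose": (1144, 41.2, 0.497),
    "1 M TMU": (999, 49.0, 0.412),
    "1 M TMU + 1 M fructose": (1067, 42.8, 0.451),
    "1 M TMU + 1 M glucose": (1068, 42.8, 0.460),
    "1 M TMU + 1 M sucrose": (1127, 37.1, 0.497),
    "1 M TMU + 1 M trehalose": (1131, 37.3, 0.511),
    "1 M NaClO4": (1068, 52.5, 0.401),
    "1 M NaClO4 + 1 M fructose": (1144, 46.7, 0.443),
    "1 M NaClO4 + 1 M glucose": (1136, 46.3, 0.448),
    "1 M NaClO4 + 1 M sucrose": (1198, 40.7, 0.487),
    "1 M NaClO4 + 1 M trehalose": (1216, 41.7, 0.506),
    "1 M GdmCl": (1022, 51.4, 0.404),
    "1 M GdmCl + 1 M fructose": (1090, 45.2, 0.443),
    "1 M GdmCl + 1 M glucose": (1091, 45.2, 0.451),
    "1 M GdmCl + 1 M sucrose": (1150, 39.5, 0.489),
    "1 M GdmCl + 1 M trehalose": (1156, 39.9, 0.504),
    "0.5 M GdmSCN": (1011, 52.8, 0.392),
    "0.5 M GdmSCN + 1 M fructose": (1079, 46.6, 0.431),
    "0.5 M GdmSCN + 1 M glucose": (1079, 46.6, 0.439),
    "0.5 M GdmSCN + 1 M sucrose": (1145, 41.3, 0.479),
    "0.5 M GdmSCN + 1 M trehalose": (1141, 41.0, 0.490),
}

TABLE3 = {
    "water": (1074, 1878, 804, None),
    "1 M fructose": (1125, 1967, 842, 38),
    "1 M glucose": (1145, 2001, 856, 52),
    "1 M sucrose": (1155, 2020, 865, 61),
    "1 M trehalose": (1223, 2138, 915, 111),
    "1 M urea": (1111, 1942, 831, 27),
    "1 M urea + 1 M fructose": (1167, 2040, 873, 69),
    "1 M urea + 1 M glucose": (1195, 2088, 893, 89),
    "1 M urea + 1 M sucrose": (1207, 2110, 903, 99),
    "1 M urea + 1 M trehalose": (1269, 2218, 949, 145),
    "1 M TMU": (1079, 1887, 808, 4),
    "1 M TMU + 1 M fructose": (1131, 1978, 847, 43),
    "1 M TMU + 1 M glucose": (1168, 2042, 874, 70),
    "1 M TMU + 1 M sucrose": (1165, 2037, 872, 68),
    "1 M TMU + 1 M trehalose": (1237, 2162, 925, 121),
    "1 M NaClO4": (1128, 1972, 844, 40),
    "1 M NaClO4 + 1 M fructose": (1209, 2114, 905, 101),
    "1 M NaClO4 + 1 M glucose": (1219, 2130, 911, 107),
    "1 M NaClO4 + 1 M sucrose": (1230, 2150, 920, 116),
    "1 M NaClO4 + 1 M trehalose": (1359, 2373, 1014, 210),
    "1 M GdmCl": (1130, 1976, 846, 42),
    "1 M GdmCl + 1 M fructose": (1187, 2076, 889, 85),
    "1 M GdmCl + 1 M glucose": (1225, 2141, 916, 112),
    "1 M GdmCl + 1 M sucrose": (1227, 2145, 918, 114),
    "1 M GdmCl + 1 M trehalose": (1309, 2288, 979, 175),
    "0.5 M GdmSCN": (1085, 1897, 812, 8),
    "0.5 M GdmSCN + 1 M fructose": (1135, 1985, 850, 46),
    "0.5 M GdmSCN + 1 M glucose": (1168, 2041, 873, 69),
    "0.5 M GdmSCN + 1 M sucrose": (1188, 2077, 889, 85),
    "0.5 M GdmSCN + 1 M trehalose": (1231, 2151, 920, 116),
}
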