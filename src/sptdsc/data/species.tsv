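name	molar_mass_g_mol	sigma_A	ions
water	18.015	2.80
fructose	180.16	6.40
glucose	180.16	6.60
sucrose	342.30	8.10
trehalose	342.30	8.30
urea	60.06	4.64
TMU	116.16	6.13
Na+	22.990	2.02
ClO4-	99.450	4.80
Gdm+	60.077	4.70
Cl-	35.453	3.62
SCN-	58.083	3.94
NaClO4	122.44		Na+:1;ClO4-:1
GdmCl	95.530		Gdm+:1;Cl-:1
GdmSCN	118.16		Gdm+:1;SCN-:1
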