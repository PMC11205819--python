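center_cm1	component	assignment	nitrogen_associated	n15_center_cm1
655.246	unknown	v (C-S) gauche	True	648.246
754.235	unknown	Symmetric breathing of tryptophan	False
810.75	nucleic acids	C-O-P-O-C in RNA backbone	False
872.62	carbohydrates	C-C stretching, Hydroxyproline	False
943.17	carbohydrates	C-O stretching; C-O-C and C-O-H deformation; alpha-helix C-C backbone	True	927.0
972.30	lipids	V (C-C) wagging	False
1008.68	proteins	C-C aromatic	False
1090.82	unknown	C-O stretching	False
1130.31	proteins	C-N stretching	True	1123.0
1269.12	lipids	Amide III random, lipids	True	1255.12
1305.86	lipids	CH3/CH2 twisting or bending mode of lipids	False
1364.78	unknown	vs (CH3) Adenine, guanine, tyrosine, tryptophan	False
1405.91	unknown	v (COO-)	False
1446.82	lipids	CH2, CH3 bending modes	False
1595.28	proteins	C=N and C=C stretching in quinoid ring	False
1609.89	proteins	Cytosine (NH2)	False
1643.04	proteins	Amide I band (protein band)	False
1663.69	lipids	(C=C) cis, lipids, fatty acids	False
2857.48	lipids	CH2 symmetric stretch of lipids	False
3017.76	lipids	v=CH of lipids	False
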