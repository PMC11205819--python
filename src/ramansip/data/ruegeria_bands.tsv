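center_cm1	component	assignment	nitrogen_associated	n15_center_cm1
743.26	amino acid	C-S stretch	False
824.35	amino acid	aromatic ring vibration	True	804.0
958.87	amino acid	C-N stretching	True	920.0
994.42	amino acid	C-C aromatic and symmetric ring breath	False
1157.26	carbohydrates	C-C, C=C band stretch	False
1231.47	unknown	Amide III, C-N stretch, N-H coupling	False
1329.66	unknown	DNA, Phospholipids, purine	False
1375.36	nucleobase	Thymine, adenine, guanine	True	1364.0
1460.45	proteins	CH2 bending mode, C-H vibrations	True	1448.0
1573.91	unknown	Amide II, nucleic acid, Peptidoglycan	False
2918.07	lipids	C-H vibrations	False
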