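center_cm1	component	assignment	nitrogen_associated	n15_center_cm1
1240.0	proteins	Amide III, protein-related	True	1228.0
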