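no	genus	name	accession	medium	coral	identity_pct
JW-1	Vibrio	Vibrio owensii	CP045859.1	LB; L1	A. hyacinthus	100
JW-2	Vibrio	Vibrio vulnificus	MN860081.1	LB	A. hyacinthus	100
JW-3	Vibrio	Vibrio coralliilyticus	CP031472.1	LB	A. hyacinthus	99
JW-4	Vibrio	Vibrio sp. Strain JC009	CP092106.1	L1	A. hyacinthus	100
JW-5	Vibrio	Vibrio alginolyticus	CP054700.1	MA2216E	G. fascicularis	99.9
JW-6	Vibrio	Vibrio rotiferianus	AP019798.1	MA2216E	G. fascicularis	99.9
JW-7	Ruegeria	Ruegeria conchae	CP031472.1	MA2216E	A. hyacinthus	100
JW-8	Ruegeria	Ruegeria sp. MR31c	HQ439523.1	MA2216E	A. hyacinthus	99
JW-9	Ruegeria	Ruegeria sp. atlantica	MW828512.1	MA2216E	A. hyacinthus	100
JW-10	Ruegeria	Ruegeria sp. LR4	KU560503.1	MA2216E	A. hyacinthus	99
JW-11	Ruegeria	Ruegeria sp. strain MP15.1	OQ435566.1	MA2216E	A. hyacinthus; G. fascicularis	99
JW-12	Ruegeria	Ruegeria arenilitoris	MG896151.1	MA2216E	G. fascicularis	99
JW-13	Ruegeria	Ruegeria lacuscaerulensis	MH283799.1	L1	G. fascicularis	99
JW-14	Bacillus	Bacillus horikoshii	DQ289065.1	MA2216E	G. fascicularis	99
JW-15	Bacillus	Bacillus weihaiensis	CP016020.1	MA2216E	G. fascicularis	100
JW-16	Bacillus	Bacillus coahuilensis	EF014447.1	MA2216E	G. fascicularis	100
JW-17	Thalassotalea	Thalassotalea euphylliae	MW828496.1	L1	A. hyacinthus; G. fascicularis	99
JW-18	Thalassotalea	Thalassomonas loyana	HQ439553.1	MA2216E	G. fascicularis	99
JW-19	Thalassotalea	Thalassomonas agarivorans	HQ439504.1	MA2216E	G. fascicularis	99
JW-20	Thalassospira	Thalassospira sp. 2ta1	FJ952805.1	MA2216E	A. hyacinthus	99
JW-21	Microbulbifer	Microbulbifer sp. Alg-AMLN-14-8	MK453424.1	MA2216E	A. hyacinthus	100
JW-22	Phaeobacter	Phaeobacter sp. strain 088	MK801649.1	MA2216E	A. hyacinthus	100
JW-23	Alteromonas	Alteromonas aestuariivivens	NR157790.1	L1	A. hyacinthus	96
JW-24	Alteromonas	Alteromonas macleodii	OX359243.1	L1; CDA	A. hyacinthus; G. fascicularis	99
JW-25	Roseovarius	Roseovarius sp.	MZ262971.1	MA2216E	A. hyacinthus	99
JW-26	Roseobacteraceae	Shima sp. LR11	KU560500.1	NSW	A. hyacinthus	100
JW-27	Roseobacteraceae	Shimia isoporae	MH283808.1	L1	G. fascicularis	100
JW-28	Marinobacter	Marinobacter sp.	MT210870.1	MA2216E	A. hyacinthus	100
JW-29	Labrenzia	Labrenzia sp.	MK493531.1	MA2216E	A. hyacinthus	99
JW-30	Psychrosphaera	Psychrosphaera sp.	MZ262895.1	L1	A. hyacinthus	100
JW-31	Microbacterium	Microbacterium esteraromaticum	MT453933.1	MA2216E	G. fascicularis	100
JW-32	Microbacterium	Microbacterium sp. OB57	JN942151.1	MA2216E	G. fascicularis	99
JW-33	Rossellomorea	Rossellomorea aquimaris	MK256784.1	MA2216E	G. fascicularis	100
JW-34	Tropicibacter	Tropicibacter sp.	MK801651.1	MA2216E	G. fascicularis	100
JW-35	Stutzerimonas	Stutzerimonas stutzeri	MT356167.1	CDA	G. fascicularis	99
JW-36	Acinetobacter	Acinetobacter seifertii	OP114754.1	CDA	G. fascicularis	99
JW-37	Acinetobacter	Acinetobacter soli	OP854766.1	CDA	G. fascicularis	100
JW-38	Enterobacter	Enterobacter cancerogenus	CP025225.1	CDA	G. fascicularis	100
JW-39	Marinomonas	Marinomonas sp.	MG099520.1	CDA	G. fascicularis	99
JW-40	Aerococcus	Aerococcus viridans	MT502756.1	MA2216E	G. fascicularis	99
JW-41	Pseudoalteromonas	Pseudoalteromonas shioyasakiensis	KU321310.1	MA2216E	G. fascicularis	99
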