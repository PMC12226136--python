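protein_id	peptide	prev_aa	next_aa	start	end	working_protease	modifications	abundance_E	abundance_EQ	enzyme	published_site	published_domain	published_log2_abundance	published_z	eq_enriched	spanning
P13611-2	GKSPPVR	V	G	27	33	trypsin		978356		ADAMTS9	V26-G27	G1	19.9	17.3	0	0
P13611-2	TVPSKFTFEEAAK	L	E	256	268	trypsin		6.2		ADAMTS9	L255-T256	G1	2.64	17.9	0	0
P13611-2	AEARRGQFE	A	S	440	448	gluc		6.3		ADAMTS9	A439-A440	GAGbeta	2.65	18.4	0	0
P13611-2	TEPTGLVLSTVMDRVVAENITQTSR	S	E	893	917	trypsin	1:acetyl	397336		ADAMTS9	S892-T893	GAGbeta	18.6	16.2	0	0
P13611-2	LWSRQE	K	V	1110	1115	gluc		140480		ADAMTS9	K1109-L1110	GAGbeta	17.1	3.25	0	0
P13611-2	EKHPEVPSAK	L	A	1479	1488	trypsin		425854		ADAMTS9	L1478-E1479	GAGbeta	18.7	16.2	0	0
P13611-2	INPETQAALIRGQDSTIAASEQQVAARIL	E	D	2023	2051	gluc	3:oxidation	262144		ADAMTS9	L2051-D2052	GAGbeta	18.0	17.7	0	0
P13611-2	LQGAHLT	R	S	2212	2218	trypsin		1.82568e+06		ADAMTS9	T2218-S2219	G3	20.8	2.06	0	0
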