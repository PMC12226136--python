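protein_id	peptide	prev_aa	next_aa	start	end	working_protease	modifications	abundance_E	abundance_EQ	enzyme	published_site	published_domain	published_log2_abundance	published_z	eq_enriched	spanning
Q9P2N4-3	FASSSSSSTSSQAHYR	A	L	86	101	trypsin		228210		ADAMTS9	A85-F86	Pro	17.8	18.6	0	0
Q9P2N4-3	VVTMAKRE	F	I	812	819	gluc		244589		ADAMTS9	F811-V812	Sp	17.9	15.0	0	0
Q9P2N4-3	EIRIGNAVVE	R	Y	819	828	gluc		280959		ADAMTS9	R818-E819	Sp	18.1	15.3	0	0
Q9P2N4-3	YSGSETAVER	E	I	829	838	trypsin		602249		ADAMTS9	E828-Y829	Sp	19.2	20.1	0	0
Q9P2N4-3	LLLQVLSVGK	E	L	849	858	trypsin		456419		ADAMTS9	E848-L849	Sp	18.8	19.6	0	0
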