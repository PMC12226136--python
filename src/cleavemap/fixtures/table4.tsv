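protein_id	peptide	prev_aa	next_aa	start	end	working_protease	modifications	abundance_E	abundance_EQ	enzyme	published_site	published_domain	published_log2_abundance	published_z	eq_enriched	spanning
P13611-3	GKSPPVR	V	G	27	33	trypsin		301124		ADAMTS1	V26-G27	G1	18.2	14.4	0	0
P13611-3	GKSPPVRGSLSGK	V	V	27	39	trypsin		978356		ADAMTS1	V26-G27	G1	19.9	3.2	0	0
P13611-3	KSPPVRGSLSGK	G	V	28	39	trypsin		322737		ADAMTS1	G27-K28	G1	18.3	3.22	0	0
P13611-3	VSLPCHF	K	S	40	46	trypsin	1:acetyl	489178		ADAMTS1	F46-S47	G1	18.9	15.0	0	0
P13611-3	CGGGLLGVR	Q	T	315	323	trypsin		851708		ADAMTS1	Q314-C315	G1	19.7	2.37	0	0
P13611-3	AATVSKWSWDEDNTTSKPLESTEPSAS	E	S	797	823	gluc	18:oxidation;24:oxidation	561918		ADAMTS1	S823-S824	GAGalpha	19.1	12.4	0	0
P13611-3	SQDILVIDQTR	P	L	1001	1011	trypsin		301124		ADAMTS1	P1000-S1001	GAGalpha	18.2	14.4	0	0
P13611-3	RIGPKVSLSPGPEQKYETE	P	G	1125	1143	gluc		3104.2		ADAMTS1	P1124-R1125	GAGalpha	11.6	17.7	0	0
P13611-3	VSLSPGPEQKYE	K	T	1130	1141	gluc		322737		ADAMTS1	K1129-V1130	GAGalpha	18.3	2.34	0	0
P13611-3	FSTIKVTVPSDITTAFSS	E	V	1196	1213	gluc		345901		ADAMTS1	S1213-V1214	GAGalpha	18.4	2.44	0	0
P13611-3	FSTIKVTVPSDITTAFSSVD	E	R	1196	1215	gluc			262144	ADAMTS1	1196-1215	GAGalpha	18.0	2.23	1	1
P13611-3	FSTIKVTVPSDITTAFSSVDRLHTTSA	E	F	1196	1222	gluc		397336		ADAMTS1	A1222-F1223	GAGalpha	18.6	12.1	0	0
P13611-3	TVACGQPPVVENAK	G	T	1539	1552	trypsin	1:acetyl;7:oxidation	645474		ADAMTS1	G1538-T1539	G3	19.3	15.2	0	0
P13611-3	PPVVENAK	Q	T	1545	1552	trypsin		2.409e+06		ADAMTS1	Q1544-P1545	G3	21.2	3.47	0	0
P13611-3	DKMGKAGVRTYGFRSPQE	G	T	220	237	gluc		1.29095e+06		ADAMTS4	G219-D220	G1	20.3	20.7	0	0
P13611-3	STGIAEKSTLRDSTTE	T	E	888	903	gluc	1:acetyl	4.42753e+07		ADAMTS4	T887-S888	GAGalpha	25.4	26.0	0	0
P13611-3	INSLIRYHCKDGFIQR	E	H	1563	1578	gluc		228210		ADAMTS4	R1578-H1579	G3	17.8	2.05	0	0
P13611-3	INSLIRYHCKDGFIQRHLPTIR	E	C	1563	1584	gluc		244589		ADAMTS4	R1584-C1585	G3	17.9	18.3	0	0
P13611-3	INSLIRYHCKDGFIQRHLPTIRCLG	E	N	1563	1587	gluc		1.95671e+06		ADAMTS4	G1587-N1588	G3	20.9	3.09	0	0
P13611-3	CYVDHLDGDVFHLTVPSKFTFEEAAKECENQDAR	Y	L	243	276	trypsin		397336		ADAMTS5	Y242-C243	G1	18.6	12.1	0	0
P13611-3	CYVDHLDGDVFHLTVPSK	Y	F	243	260	trypsin		322737		ADAMTS5	Y242-C243	G1	18.3	2.38	0	0
P13611-3	TVPSKFTFEEAAKE	L	C	256	269	gluc		345901		ADAMTS5	L255-T256	G1	18.4	13.8	0	0
P13611-3	AATVSKWSWDEDNTTSKPLESTEPSAS	E	S	797	823	gluc	18:oxidation;24:oxidation	691802		ADAMTS5	S823-S824	GAGalpha	19.4	14.6	0	0
P13611-3	VEDVDLSKPVSTVPQF	E	A	928	943	gluc		602249		ADAMTS5	F943-A944	GAGalpha	19.2	3.33	0	0
P13611-3	QDILVIDQTRLE	S	A	1002	1013	gluc	1:acetyl	280959		ADAMTS5	S1001-Q1002	GAGalpha	18.1	13.5	0	0
P13611-3	VLGEPSQDILVI	E	D	996	1007	gluc		3.17869e+06		ADAMTS5	I1007-D1008	GAGalpha	21.6	16.2	0	0
P13611-3	RTWDAAERE	R	C	1434	1442	gluc		172950		ADAMTS5	R1433-R1434	G3	17.4	13.0	0	0
P13611-3	LQGAHLT	R	S	1445	1451	trypsin		524288		ADAMTS5	T1451-S1452	G3	19.0	12.4	0	0
P13611-3	TVACGQPPVVENAK	G	T	1539	1552	trypsin	1:acetyl;7:oxidation	912838		ADAMTS5	G1538-T1539	G3	19.8	12.9	0	0
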