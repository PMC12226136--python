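protein_id	peptide	prev_aa	next_aa	start	end	working_protease	modifications	abundance_E	abundance_EQ	enzyme	published_site	published_domain	published_log2_abundance	published_z	eq_enriched	spanning
P13611-3	GKSPPVR	V	G	27	33	trypsin		741455		ADAMTS9	V26-G27	G1	19.5	19.4	0	0
P13611-3	EVDKNGKDLKE	I	T	70	80	gluc		301124		ADAMTS9	I69-E70	G1	18.2	11.2	0	0
P13611-3	FLRIKWSKI	E	E	61	69	gluc		1.70342e+06		ADAMTS9	I69-E70	G1	20.7	12.9	0	0
P13611-3	FLRIKWSKIEVDKN	E	G	61	74	gluc		561918		ADAMTS9	N74-G75	G1	19.1	2.29	0	0
P13611-3	AAKECENQDARL	E	A	266	277	gluc		262144		ADAMTS9	L277-A278	G1	18.0	11.2	0	0
P13611-3	VLQSTTGVSH	E	Y	459	468	gluc		741455		ADAMTS9	H468-Y469	GAGalpha	19.5	2.46	0	0
P13611-3	VITVSKTSEDTIHTHLEDL	E	E	579	597	gluc		1.2045e+06		ADAMTS9	L597-E598	GAGalpha	20.2	3.46	0	0
P13611-3	IELFPYSGDKIL	E	V	653	664	gluc		370728		ADAMTS9	L664-V665	GAGalpha	18.5	11.5	0	0
P13611-3	LFPYSGDKIL	E	V	655	664	gluc		1.82568e+06		ADAMTS9	L664-V665	GAGalpha	20.8	13.0	0	0
P13611-3	FTLIPDSTQKQ	E	L	854	864	gluc		489178		ADAMTS9	Q864-L865	GAGalpha	18.9	11.8	0	0
P13611-3	FTLIPDSTQKQL	E	E	854	865	gluc		301124		ADAMTS9	L865-E866	GAGalpha	18.2	11.3	0	0
P13611-3	LTGSERVPVLE	L	T	1081	1091	gluc		228210		ADAMTS9	L1080-L1081	GAGalpha	17.8	11.1	0	0
P13611-3	FSTIKVTVPSDITTAFSSVDRL	E	H	1196	1217	gluc		456419		ADAMTS9	L1217-H1218	GAGalpha	18.8	11.7	0	0
P13611-3	FAHRRTWDAAERE	Y	C	1430	1442	gluc		561918		ADAMTS9	Y1429-F1430	G3	19.1	2.19	0	0
P13611-3	RTWDAAERE	R	C	1434	1442	gluc		262144		ADAMTS9	R1433-R1434	G3	18.0	11.2	0	0
P13611-3	CRLQGAHL	E	T	1443	1450	gluc	1:pyroglu	322737		ADAMTS9	L1450-T1451	G3	18.3	11.3	0	0
P13611-3	CRLQGAHL	E	T	1443	1450	gluc		1.3836e+06		ADAMTS9	L1450-T1451	G3	20.4	12.7	0	0
P13611-3	LQGAHLT	R	S	1445	1451	trypsin		1.12384e+06		ADAMTS9	T1451-S1452	G3	20.1	2.0	0	0
P13611-3	LQGAHLTSILSHEEQMFVN	R	R	1445	1463	trypsin		645474		ADAMTS9	N1463-R1464	G3	19.3	2.11	0	0
P13611-3	QWIGLNDKMFE	Y	H	1470	1480	gluc	9:oxidation	691802		ADAMTS9	Y1469-Q1470	G3	19.4	12.1	0	0
P13611-3	QMFVNRVGHDY	E	Q	1459	1469	gluc	1:pyroglu;2:oxidation	301124		ADAMTS9	Y1469-Q1470	G3	18.2	11.3	0	0
P13611-3	QMFVNRVGHDY	E	Q	1459	1469	gluc	1:pyroglu	370728		ADAMTS9	Y1469-Q1470	G3	18.5	2.46	0	0
P13611-3	QMFVNRVGHDYQWIGLN	E	D	1459	1475	gluc	1:pyroglu	244589		ADAMTS9	N1475-D1476	G3	17.9	11.1	0	0
P13611-3	QMFVNRVGHDYQWIGLN	E	D	1459	1475	gluc	1:pyroglu;2:oxidation	301124		ADAMTS9	N1475-D1476	G3	18.2	11.3	0	0
P13611-3	NWRPNQPDSF	E	F	1495	1504	gluc		489178		ADAMTS9	F1504-F1505	G3	18.9	11.8	0	0
P13611-3	HLTYTCKKGTVACGQPPVVE	Y	N	1530	1549	gluc		425854		ADAMTS9	Y1529-H1530	G3	18.7	11.6	0	0
P13611-3	NGQWNDVPCNYHLT	E	Y	1519	1532	gluc		978356		ADAMTS9	T1532-Y1533	G3	19.9	2.44	0	0
P13611-3	QMFVNRVGHDYQWIGLNDKMFE	E	H	1459	1480	gluc			370728	ADAMTS9	1459-1480	G3	18.5	11.7	1	1
P13611-3	QMFVNRVGHDYQWIGLNDKMFE	E	H	1459	1480	gluc	2:oxidation		561918	ADAMTS9	1459-1480	G3	19.1	12.1	1	1
P13611-3	QMFVNRVGHDYQWIGLNDKMFE	E	H	1459	1480	gluc	1:pyroglu;2:oxidation		301124	ADAMTS9	1459-1480	G3	18.2	11.5	1	1
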