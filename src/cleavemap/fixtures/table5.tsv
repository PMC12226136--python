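protein_id	peptide	prev_aa	next_aa	start	end	working_protease	modifications	abundance_E	abundance_EQ	enzyme	published_site	published_domain	published_log2_abundance	published_z	eq_enriched	spanning
P21810	NDISELRK	N	D	100	107	trypsin		2.24767e+06		ADAMTS9	N99-N100	LRR1	21.1	3.6	0	0
P21810	EISPDTTLLDLQNNDISEL	K	R	87	105	trypsin		456419		ADAMTS9	L105-R106	LRR2	18.8	6.42	0	0
P21810	GLQHLYAL	K	V	112	119	trypsin		322737		ADAMTS9	L119-V120	LRR2	18.3	15.4	0	0
P21810	PSSLVELR	L	I	158	165	trypsin		2.21377e+07		ADAMTS9	L157-P158	LRR4	24.4	4.47	0	0
P21810	NHLVEIPPNLPS	K	S	148	159	trypsin		262144		ADAMTS9	S159-S160	LRR4	18.0	15.2	0	0
P21810	NHLVEIPPNLPSS	K	L	148	160	trypsin		1.3836e+06		ADAMTS9	S160-L161	LRR4	20.4	2.45	0	0
P21810	SLSFLPTLR	G	E	272	280	trypsin		645474		ADAMTS9	G271-S272	LRR9	19.3	16.2	0	0
P21810	DNNKLAR	L	V	285	291	trypsin		3.17869e+06		ADAMTS9	L284-D285	LRR9	21.6	18.1	0	0
P21810	PSGLPDLK	V	L	293	300	trypsin		5.0859e+07		ADAMTS9	V292-P293	LRR10	25.6	8.84	0	0
P21810	QFGNYK	I	K	362	367	trypsin		456419		ADAMTS9	I361-Q362	LRR12	18.8	15.7	0	0
P21810	SVPKEISPDTTLLDLQNNDISE	K	L	83	104	trypsin		370728		ADAMTS1	E104-L105	LRR2	18.5	2.22	0	0
P21810	EISPDTTLLDLQNNDISE	K	L	87	104	trypsin		322737		ADAMTS1	E104-L105	LRR2	18.3	12.8	0	0
P21810	DDFKGLQH	K	L	108	115	trypsin		456419		ADAMTS1	H115-L116	LRR2	18.8	2.55	0	0
P21810	NHLVEIPPNLPSS	K	L	148	160	trypsin		5.53442e+06		ADAMTS1	S160-L161	LRR4	22.4	2.18	0	0
P21810	NHLVEIPPNLPSSLVE	K	L	148	163	trypsin		2.37266e+07		ADAMTS1	E163-L164	LRR4	24.5	3.78	0	0
P21810	LRIHDNR	E	I	164	170	trypsin		691802		ADAMTS1	E163-L164	LRR4	19.4	13.5	0	0
P21810	NHLVEIPPNLPSSLVELRIHDNRIR	K	K	148	172	trypsin			322737	ADAMTS1	148-172	LRR4	18.3	10.9	1	1
P21810	FDGLKLNYLR	A	I	205	214	trypsin		1.48291e+06		ADAMTS1	A204-F205	LRR6	20.5	2.18	0	0
P21810	LHLDHNKIQAIELEDLLR	E	Y	234	251	trypsin		2.96582e+06		ADAMTS1	E233-L234	LRR7	21.5	3.06	0	0
P21810	ISEAKLTGIPKDLPETLNELHLDHNK	R	I	215	240	trypsin			397336	ADAMTS1	215-240	LRR7	18.6	2.07	1	1
P21810	DLPETLNELHLD	K	H	226	237	trypsin		691802		ADAMTS1	D237-H238	LRR7	19.4	2.76	0	0
P21810	DLPETLNELHLDHNKIQAIELED	K	L	226	248	trypsin		1.82568e+06		ADAMTS1	D248-L249	LRR8	20.8	2.32	0	0
P21810	RLGLGHNQIR	Y	M	257	266	trypsin		7.30271e+06		ADAMTS1	Y256-R257	LRR8	22.8	4.95	0	0
P21810	GSLSFLPTLR	N	E	271	280	trypsin		978356		ADAMTS1	N270-G271	LRR9	19.9	3.03	0	0
P21810	LRELHLDNNK	T	L	279	288	trypsin		602249		ADAMTS1	T278-L279	LRR9	19.2	3.5	0	0
P21810	EKAFSPLR	H	K	131	138	trypsin		2.24767e+06		ADAMTS4	H130-E131	LRR3	21.1	3.17	0	0
P21810	PKDLPETLNELHLDHNK	I	I	224	240	trypsin		1.29095e+06		ADAMTS4	I223-P224	LRR7	20.3	2.06	0	0
P21810	SKIHEKAFSPLR	I	K	127	138	trypsin		6.81367e+06		ADAMTS5	I126-S127	LRR2/LRR3	22.7	2.45	0	0
P21810	KIHEKAFSPLR	S	K	128	138	trypsin		4.49534e+06		ADAMTS5	S127-K128	LRR3	22.1	3.35	0	0
P21810	LYISKNHLVEIPPNLPSSLVELRIHD	K	N	143	168	trypsin		1.2045e+06		ADAMTS5	D168-N169	LRR4	20.2	3.02	0	0
P21810	AKLTGIPK	E	D	218	225	trypsin		741455		ADAMTS5	E217-A218	LRR6	19.5	2.19	0	0
P21810	PETLNELHLDHNKIQAIELEDLLRYSK	L	L	228	254	trypsin		978356		ADAMTS5	L227-P228	LRR7	19.9	2.0	0	0
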