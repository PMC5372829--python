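gene_name	gene_id	subfamily	past_percent	sp	gpi	ap_repeats	pa_repeats	sp_repeats	tp_repeats	length	chromosome	subgenome	block	at_gene	at_id	high_confidence
BrAGP1.1	Bra024284	classical	59	yes	yes	10	16	20	4	124	A06	LF	X	AtAGP1	At5g64310	yes
BrAGP1.2	Bra031924	classical	56	yes	yes	8	14	24	2	130	A02	MF1	X	AtAGP1	At5g64310	yes
BrAGP2.1	Bra038521	classical	62	yes	yes	14	6	16	4	132	A09	LF	I	AtAGP2	At2g22470	yes
BrAGP2.2	Bra030234	classical	61	yes	yes	16	10	14	4	132	A04	MF1	I	AtAGP2	At2g22470	yes
BrAGP3.1	Bra011806	classical	61	yes	yes	14	14	18	8	143	A01	LF	U	AtAGP3	At4g40090	yes
BrAGP3.2	Bra010639	classical	60	yes	yes	14	12	18	10	143	A08	MF2	U	AtAGP3	At4g40090	yes
BrAGP4.1	Bra009032	classical	71	yes	yes	18	24	6	20	143	A10	LF	R	AtAGP4	At5g10430	yes
BrAGP4.2	Bra006060	classical	72	yes	yes	14	20	8	18	141	A03	MF1	R	AtAGP4	At5g10430	yes
BrAGP4.3	Bra028587	classical	71	yes	yes	20	20	6	16	139	A02	MF2	R	AtAGP4	At5g10430	yes
BrAGP6	Bra008762	classical	66	yes	yes	14	8	14	6	152	A10	LF	R	AtAGP6	At5g14380	yes
BrAGP9.1	Bra013116	classical	70	yes	yes	14	22	14	18	179	A03	MF2	H	AtAGP9	At2g14890	yes
BrAGP9.2	Bra039829	classical	67	yes	yes	14	18	16	16	166	Scaffold000178	unplaced		AtAGP9	At2g14890	yes
BrAGP10.1	Bra038390	classical	62	yes	no	6	2	8	6	81	A09	LF	P	AtAGP10	At4g09030	no
BrAGP10.2	Bra000670	classical	65	yes	yes	12	8	12	10	126	A03	MF1	P	AtAGP10	At4g09030	yes
BrAGP11.1	Bra000995	classical	59	yes	yes	16	4	8	4	136	A03	MF2	H	AtAGP11	At3g01700	yes
BrAGP11.2	Bra040548	classical	63	yes	yes	18	6	10	4	138	Scaffold000217	unplaced		AtAGP11	At3g01700	yes
BrAGP25	Bra002180	classical	50	yes	yes	8	4	14	2	135	A10	LF	R	AtAGP25	At5g18690	yes
BrAGP26	Bra021448	classical	52	yes	yes	4	2	20	2	140	A04	MF1	J	AtAGP26	At2g47930	yes
BrAGP27	Bra040224	classical	55	yes	yes	8	6	8	0	126	A01	MF1	F	AtAGP27	At3g06360	yes
BrAGP50.1	Bra032796	classical	46	yes	yes	4	0	8	2	119	A09	LF	B	AtAGP50	At1g24520	no
BrAGP50.2	Bra010966	classical	48	yes	yes	6	2	8	2	117	A08	MF1	B	AtAGP50	At1g24520	no
BrAGP50.3	Bra012505	classical	47	yes	yes	4	2	10	0	119	A07	MF2	B	AtAGP50	At1g24520	no
BrAGP52	Bra027649	classical	46	no	no	8	24	16	24	420	A09	MF2	D	AtAGP52	At1g63530	no
BrAGP53	Bra027648	classical	46	yes	no	12	16	14	32	618	A09	MF2	D	AtAGP53	At1g63540	no
BrAGP54.1	Bra011948	classical	53	yes	yes	12	18	54	2	234	A07	LF	I	AtAGP54	At2g28440	yes
BrAGP54.2	Bra035700	classical	44	yes	yes	2	8	24	4	186	A04	MF1	I	AtAGP54	At2g28440	no
BrAGP55	Bra004882	classical	59	no	yes	46	38	26	22	784	A05	LF	J	AtAGP55	At2g45000	no
BrAGP57	Bra038294	classical	43	yes	yes	8	8	24	2	168	A06	LF	M	AtAGP57	At3g45230	no
BrAGP58.1	Bra040103	classical	56	no	no	8	4	16	8	135	A01	LF	U	AtAGP58	At4g16980	no
BrAGP58.2	Bra021074	classical	58	no	yes	12	2	16	4	130	A08	MF2	U	AtAGP58	At4g16980	no
BrAGP59	Bra028633	classical	53	yes	yes	6	4	14	6	115	A02	MF2	R			yes
BrAGP60	Bra035584	classical	60	yes	yes	24	24	50	18	339	A02	MF2	W			yes
BrAGP61	Bra036401	classical	70	yes	yes	14	16	18	14	171	A07	LF	H			yes
BrAGP12.1	Bra027425	ag_peptide	44	yes	yes	2	4	4	0	61	A05	LF	F	AtAGP12	At3g13520	yes
BrAGP12.2	Bra039397	ag_peptide	47	yes	yes	2	4	4	0	62	Scaffold000164	unplaced		AtAGP12	At3g13520	yes
BrAGP13.1	Bra026448	ag_peptide	46	yes	yes	4	4	2	0	59	A01	LF	U	AtAGP13	At4g26320	yes
BrAGP13.2	Bra019114	ag_peptide	42	yes	yes	4	2	2	0	59	A03	MF1	U	AtAGP13	At4g26320	yes
BrAGP14	Bra002808	ag_peptide	43	yes	yes	4	2	2	0	60	A10	LF	W	AtAGP14	At5g56540	yes
BrAGP15.1	Bra008940	ag_peptide	53	yes	yes	4	2	4	0	64	A10	LF	R	AtAGP15	At5g11740	yes
BrAGP15.2	Bra006115	ag_peptide	53	yes	yes	2	2	6	0	64	A03	MF1	R	AtAGP15	At5g11740	yes
BrAGP15.3	Bra023339	ag_peptide	52	yes	yes	4	2	4	0	64	A02	MF2	R	AtAGP15	At5g11740	yes
BrAGP16.1	Bra004546	ag_peptide	42	yes	yes	6	4	0	0	73	A05	LF	J	AtAGP16	At2g46330	yes
BrAGP16.2	Bra000419	ag_peptide	42	yes	yes	6	4	0	0	73	A03	MF2	J	AtAGP16	At2g46330	yes
BrAGP20	Bra014427	ag_peptide	40	yes	yes	4	2	4	0	68	A04	MF1	N	AtAGP20	At3g61640	yes
BrAGP21.1	Bra037993	ag_peptide	46	yes	yes	4	4	2	0	59	A06	LF	C	AtAGP21	At1g55330	yes
BrAGP21.2	Bra011914	ag_peptide	46	yes	yes	4	4	2	0	59	A07	MF2	C	AtAGP21	At1g55330	yes
BrAGP21.3	Bra030868	ag_peptide	47	yes	yes	4	4	2	0	58	A08	MF1	C	AtAGP21	At1g55330	yes
BrAGP22.1	Bra003071	ag_peptide	38	yes	yes	4	4	4	0	63	A10	LF	W	AtAGP22	At5g53250	yes
BrAGP22.2	Bra029086	ag_peptide	38	yes	yes	4	4	4	0	63	A03	MF1	W	AtAGP22	At5g53250	yes
BrAGP22.3	Bra022641	ag_peptide	38	yes	yes	4	4	4	0	63	A02	MF2	W	AtAGP22	At5g53250	yes
BrAGP23.1	Bra007349	ag_peptide	46	no	yes	4	6	0	0	61	A09	LF	N	AtAGP23	At3g57690	no
BrAGP23.2	Bra014611	ag_peptide	44	no	yes	4	6	0	0	61	A04	MF1	N	AtAGP23	At3g57690	no
BrAGP23.3	Bra003296	ag_peptide	43	yes	yes	4	6	0	0	61	A07	MF2	N	AtAGP23	At3g57690	yes
BrAGP24	Bra025551	ag_peptide	37	yes	yes	4	6	2	0	67	A04	LF	S	AtAGP24	At5g40730	yes
BrAGP40.1	Bra031236	ag_peptide	45	yes	yes	4	4	2	0	64	A05	LF	F	AtAGP40	At3g20865	yes
BrAGP40.2	Bra023919	ag_peptide	47	yes	yes	4	4	2	0	64	A01	MF1	F	AtAGP40	At3g20865	yes
BrAGP42	Bra030409	ag_peptide	30	yes	no	0	2	2	0	77	A05	MF2	C	AtAGP42	At1g51915	no
BrAGP43.1	Bra016902	ag_peptide	44	yes	yes	4	6	0	0	61	A04	MF1	J	AtAGP43	At2g41905	yes
BrAGP43.2	Bra000244	ag_peptide	44	yes	yes	4	6	0	0	61	A03	MF2	J	AtAGP43	At2g41905	yes
BrAGP44	Bra000992	ag_peptide	39	yes	yes	4	2	4	0	90	A03	MF2	F	AtAGP44	At3g01730	yes
BrAGP45	Bra008874	ag_peptide	46	yes	no	2	0	4	0	76	A10	LF	R	AtAGP45	At5g12880	no
BrAGP17	Bra039184	lys_rich	68	yes	yes	44	42	56	12	305	A09	LF	I	AtAGP17	At2g23130	yes
BrAGP18.1	Bra011767	lys_rich	62	yes	yes	20	14	26	4	178	A01	LF	U	AtAGP18	At4g37450	yes
BrAGP18.2	Bra017823	lys_rich	65	yes	yes	30	30	28	10	202	A03	MF1	U	AtAGP18	At4g37450	yes
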