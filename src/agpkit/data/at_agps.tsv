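at_gene	at_id	subfamily	block	status
AtAGP1	At5g64310	classical	X	conserved
AtAGP2	At2g22470	classical	I	conserved
AtAGP3	At4g40090	classical	U	conserved
AtAGP4	At5g10430	classical	R	conserved
AtAGP5	At1g35230	classical	B	lost_in_brapa
AtAGP6	At5g14380	classical	R	conserved
AtAGP7	At5g65390	classical	X	lost_in_brapa
AtAGP9	At2g14890	classical	H	conserved
AtAGP10	At4g09030	classical	P	conserved
AtAGP11	At3g01700	classical	H	conserved
AtAGP25	At5g18690	classical	R	conserved
AtAGP26	At2g47930	classical	J	conserved
AtAGP27	At3g06360	classical	F	conserved
AtAGP50	At1g24520	classical	B	conserved
AtAGP51	At1g31250	classical	B	lineage1_specific
AtAGP52	At1g63530	classical	D	conserved
AtAGP53	At1g63540	classical	D	conserved
AtAGP54	At2g28440	classical	I	conserved
AtAGP55	At2g45000	classical	J	conserved
AtAGP56	At3g22070	classical	F	lost_in_brapa
AtAGP57	At3g45230	classical	M	conserved
AtAGP58	At4g16980	classical	U	conserved
AtAGP12	At3g13520	ag_peptide	F	conserved
AtAGP13	At4g26320	ag_peptide	U	conserved
AtAGP14	At5g56540	ag_peptide	W	conserved
AtAGP15	At5g11740	ag_peptide	R	conserved
AtAGP16	At2g46330	ag_peptide	J	conserved
AtAGP20	At3g61640	ag_peptide	N	conserved
AtAGP21	At1g55330	ag_peptide	C	conserved
AtAGP22	At5g53250	ag_peptide	W	conserved
AtAGP23	At3g57690	ag_peptide	N	conserved
AtAGP24	At5g40730	ag_peptide	S	conserved
AtAGP40	At3g20865	ag_peptide	F	conserved
AtAGP41	At5g24105	ag_peptide	Q	lost_in_brapa
AtAGP42	At1g51915	ag_peptide	C	conserved
AtAGP43	At2g41905	ag_peptide	J	conserved
AtAGP44	At3g01730	ag_peptide	F	conserved
AtAGP45	At5g12880	ag_peptide	R	conserved
AtAGP17	At2g23130	lys_rich	I	conserved
AtAGP18	At4g37450	lys_rich	U	conserved
AtAGP19	At1g68725	lys_rich	E	lost_in_brapa
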