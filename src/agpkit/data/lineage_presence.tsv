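at_id	A.thaliana	A.lyrata	C.rubella	C.sativa	B.rapa	B.napus	B.oleracea	T.halophila	T.salsuginea	S.irio	S.parvula	A.arabicum
At1g35230	1	1	1	1	0	1	1	1	1	1	1	1
At5g65390	1	1	1	1	0	1	1	1	1	1	1	1
At1g68725	1	1	1	1	0	1	1	1	1	1	1	1
At5g24105	1	1	1	1	0	1	1	1	1	1	1	1
At1g31250	1	1	1	1	0	0	0	0	0	0	0	0
At3g22070	1	1	1	1	0	1	1	1	1	1	1	1
At5g64310	1	1	1	1	1	1	1	1	1	1	1	1
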