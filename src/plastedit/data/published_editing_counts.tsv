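conversion	L_chlorophorum	TGD	MGD
A>U	0	0	1
A>G	118	88	15
A>C	0	0	0
U>A	0	1	0
U>G	0	0	0
U>C	59	82	0
G>A	5	0	1
G>U	0	0	0
G>C	5	0	0
C>A	0	0	0
C>U	1	6	1
C>G	0	0	0
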