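	1	2	3	4	5	6	7
A	1.0	-1.0	0.0	0.0	0.0	0.0	0.0
B	0.0	1.0	-1.0	0.0	0.0	0.0	-1.0
C	0.0	0.0	1.0	0.0	-1.0	-1.0	0.0
D	0.0	0.0	0.0	1.0	0.0	0.0	-1.0
A_ext	-1.0	0.0	0.0	0.0	0.0	0.0	0.0
E_ext	0.0	0.0	0.0	-1.0	0.0	1.0	0.0
F_ext	0.0	0.0	0.0	0.0	1.0	0.0	0.0
biomass	0.0	0.0	0.0	0.0	0.0	0.0	1.0
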