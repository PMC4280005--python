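reaction_id	reversible
1	0
2	0
3	1
4	0
5	0
6	1
7	0
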