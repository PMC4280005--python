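metabolite_id	role
A	internal
B	internal
C	internal
D	internal
A_ext	external
E_ext	external
F_ext	external
biomass	biomass
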