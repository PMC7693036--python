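entry	is_reference	metal_binding_1	metal_binding_2	substrate_binding	transition_state
CanonicalGC	1	D	D	E	N
Cop6	0	D	D	E	N
KnRh1	0	D	D	E	R
Cop5	0	G	S	A	G
Vop5	0	A	T	V	S
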