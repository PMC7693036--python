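entry	is_reference	proton_acceptor	proton_acceptor_pos	proton_donor	proton_donor_pos	dc_gate	dc_gate_pos	stabilizer	stabilizer_pos	retinal_attachment	retinal_attachment_pos
ChR2	1	D	253	D	156	C	128	R	120	K	257
KnRh3	0	D	250	D	154	C	126	R	118	K	254
TsRh1	0	D	236	D	139	C	111	R	103	K	240
GpRh1	0	D	213	D	116	C	88	R	80	K	217
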