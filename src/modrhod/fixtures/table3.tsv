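label	is_reference	residue_name	residue	polarity	shift
Green PR	1	Leucine	L	Non-Polar	Green
Blue PR	1	Glutamine	Q	Polar	Blue
KnRh3, TsRh1 and GpRh3	0	Isoleucine	I	Non-polar	Green
Cop8-12, GpRh2, ApRh1, AsRh2	0	Isoleucine	I	Non-polar	Green
MspRh1, MpuRh1, AsRh3-4, OtRh1-2, OlRh1-4, DsRh1, GtRh2,3	0	Leucine	L	Non-polar	Green
Cop5-7, Vop5-7, GpRh3-5, GtRh4-10, AsRh1, MspRh2, MpuRh2, CsRh1, BgRh1-2, KnRh1-2	0	Methionine	M	Non-polar	Green
GtRh1	0	Aspartate	D	Acidic	unknown
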