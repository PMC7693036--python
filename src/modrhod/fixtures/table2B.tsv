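entry	is_reference	proton_acceptor	proton_acceptor_pos	acceptor_stabilizer	acceptor_stabilizer_pos	retinal_pocket	retinal_pocket_pos	proton_donor	proton_donor_pos	counterion	counterion_pos	proton_release_194	proton_release_194_pos	proton_release_204	proton_release_204_pos	retinal_attachment	retinal_attachment_pos
BR	1	D		T		T		D		D		E		E		K
HR	1	T	90	S	94	T	95	A	101	D	217	E	198	T	209	K	221
KR2	1	N	112	D	116	V	117	Q	123	D	251	L	227	R	243	K	255
ASR1	1	D	75	T	79	T	80	S	86	P	206	S	188	D	198	K	210
SR2	1	D	75	T	79	T	80	F	86	D	201	L	188	D	193	K	205
RhoGC	1	E	254	T	258	C	259	L	265	D	380	S	364	A	372	K	384
RhoPDE	1	E	164	T	168	C	167	W	175	D	292	Q	276	G	284	K	296
AsRh4	0	D	2593	T	2597	T	2598	D	2604	D	2718	G	2701	E	2710	K	2722
GtRh1	0	F	152	S	156	T	157	I	163	D	297	G	280	K	289	K	301
GtRh2/3	0	D	95	T	99	C	100	T	106	D	248	T	232	E	240	K	252
Cop5	0	M	113	T	117	T	118	L	124	D	239	M	223	E	231	K	243
Cop6	0	Q	170	T	174	T	175	I	181	N	294	V	279	-		K	298
Cop7	0	Q	161	S	165	T	166	M	172	D	287	W	271	E	279	K	291
Cop8	0	L	67	T	71	A	72	I	78	D	194	D	178	S	186	K	198
Cop9-10	0	L	141	T	145	A	146	I	152	D	268	D	252	S	260	K	272
Cop11	0	C	95	T	99	T	100	L	106	D	279	L	263	E	271	K	283
Cop12	0	C	95	T	99	T	100	L	106	D	221	L	205	E	213	K	225
Vop5	0	M	157	T	161	T	162	L	168	D	283	L	267	E	275	K	287
Vop6	0	Q	153	T	157	T	158	I	164	N	278	L	263	-		K	282
Vop7	0	Q	147	S	151	T	152	M	158	D	272	W	256	E	264	K	276
MspRh1	0	E	140	T	144	T	145	I	151	D	284	F	268	Q	276	K	288
MspRh2	0	E	142	G	146	T	147	L	153	D	299	S	283	L	291	K	303
MpuRh1	0	E	140	T	144	T	145	I	151	D	300	F	284	Q	292	K	304
MpuRh2	0	S	151	S	155	T	156	L	162	D	328	A	312	A	320	K	332
GtRh4	0	Q	92	T	96	T	97	V	103	D	225	S	209	Y	217	K	229
GtRh5	0	Q	222	T	226	T	227	V	233	D	355	G	339	Y	347	K	359
GtRh6	0	Q	234	T	238	T	239	V	245	D	367	G	351	Y	359	K	371
GtRh7	0	Q	116	T	120	T	121	V	127	D	249	S	233	Y	241	K	253
GtRh8	0	Q	226	T	230	T	231	V	237	D	359	L	343	Y	351	K	363
GtRh9	0	Q	229	T	233	T	234	I	240	D	362	L	346	Y	354	K	366
GtRh10	0	Q	192	T	196	T	197	V	203	D	325	L	309	F	317	K	329
BgRh1/2	0	E	173	T	177	T	178	S	184	D	302	L	286	E	294	K	306
OtRh1	0	E	181	T	185	T	186	L	192	D	314	M	298	E	306	K	318
OtRh2	0	E	476	T	480	T	481	L	487	D	609	M	593	E	601	K	613
OlRh1	0	E	204	T	208	T	209	L	215	D	337	L	321	E	329	K	341
OlRh2	0	E	260	T	264	T	265	L	271	D	393	L	377	E	385	K	397
OlRh3	0	E	188	T	192	T	193	L	199	D	321	L	305	E	313	K	325
OlRh4	0	E	115	T	119	T	120	L	126	D	248	L	232	E	240	K	252
DsRh1	0	Q	140	S	144	T	145	M	151	D	268	L	252	E	260	K	272
GpRh2	0	C	91	T	95	T	96	L	102	D	217	L	201	E	209	K	221
GpRh3	0	Q	85	T	89	T	90	I	96	N	209	A	194	-		K	213
GpRh4	0	M	67	T	71	T	72	L	78	D	193	L	177	E	185	K	197
GpRh5	0	Q	1412	S	1416	T	1417	M	1423	D	1537	L	1521	E	1529	K	1541
CsRh1	0	M	144	A	148	T	149	T	155	D	269	L	253	E	261	K	273
ApRh1	0	M	67	A	71	T	72	T	78	D	192	A	176	E	184	K	196
AsRh1	0	N	122	T	126	T	127	L	133	N	248	L	232	T	240	K	252
AsRh2	0	N	123	T	127	T	128	L	134	N	249	L	233	S	241	K	253
AsRh3	0	Q	78	T	82	T	83	V	89	N	203	L	187	C	195	K	207
KnRh1	0	Q	166	T	170	T	171	M	177	D	292	L	276	E	284	K	296
KnRh2	0	Q	95	T	99	T	100	L	106	E	221	T	205	E	213	K	225
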