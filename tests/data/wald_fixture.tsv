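gene_id	t1	t2	t3	t4	t5	t6	r1	r2	r3	r4	r5	r6
g01	3	7	0	2	1	5	1	3	3	1	4	0
g02	29	37	14	17	9	11	29	23	35	15	66	39
g03	51	70	32	57	51	31	16	36	19	10	16	26
g04	103	116	82	141	80	69	471	379	397	353	415	345
g05	337	489	487	349	412	342	406	322	372	395	417	507
g06	1373	867	930	871	786	776	161	303	281	93	168	189
g07	37	23	17	25	8	23	51	61	49	35	25	36
g08	106	69	115	101	99	66	80	69	139	100	86	73
g09	344	256	213	277	243	226	107	191	261	204	162	235
g10	7	13	17	14	8	27	70	36	62	21	23	40
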