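family	pvu	gma	mtr
156	6	7	9
157	1	0	0
159	6	4	1
160	2	1	5
162	1	1	1
164	2	1	4
166	2	2	8
167	5	7	1
168	1	1	1
169	6	5	17
171	3	3	7
172	2	3	1
319	4	3	2
390	3	3	1
393	1	3	2
394	1	2	0
395	1	0	18
396	5	5	2
397	2	0	0
398	1	2	3
399	3	0	17
408	2	0	0
479	1	0	0
482	3	2	0
1510	1	2	2
1511	1	1	0
1514	1	2	0
1515	1	1	0
2111	1	0	19
2118	2	0	1
2119	1	1	1
2199	2	0	1
4376	1	1	1
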