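family	name	sequence	length	LL	FL	RL	SL	total
166	aly-miR166b*	GGACUGUUGUCUGGCUCGAGG	21	233	0	5	3	241
166	aly-miR166g*	GGAAUGUUGUUUGGCUCGAGG	21	38	143	186	257	624
166	zma-miR166a*	GGAAUGUUGUCUGGCUCGGGG	21	26	3	11	7	47
166	gma-miR166a-5p	GGAAUGUUGUCUGGCUCGAGG	21	36866	3839	6253	23902	70860
166	zma-miR166m*	GGAAUGUUGGCUGGCUCGAGG	21	55	655	50	3363	4123
167	ahy-miR167-3p	AGAUCAUGUGGCAGUUUCACC	21	155	16	84	11	266
168	aly-miR168a*	CCCGCCUUGCAUCAACUGAAU	21	80	22	8	3	113
171	aly-MIR171a*	UAUUGGCCUGGUUCACUCAGA	21	179	710	1	543	1433
172	aly-miR172c*	GGAGCAUCAUCAAGAUUCACA	21	10	352	19	1	382
390	aly-miR390a*	CGCUAUCCAUCCUGAGUUUCA	21	149	524	69	10	752
390	gma-miR390a-3p	CGCUAUCCAUCCUGAGUUUC	20	14	3	0	2	19
396	aly-miR396a*	GUUCAAUAAAGCUGUGGGAAG	21	267	306	3931	791	5295
482	gma-miR482a-5p	AGAAUUUGUGGGAAUGGGCUGA	22	0	17	1	1	19
482	pvu-miR482*	GGAAUGGGCUGAUUGGGAAGCA	22	1185	6	440	10	1641
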