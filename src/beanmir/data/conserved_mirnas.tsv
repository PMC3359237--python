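family	name	sequence	length	LL	FL	RL	SL	total
156	ahy-miR156a	UGACAGAAGAGAGAGAGCAC	20	56	15	8	41	120
156	ahy-miR156c	UUGACAGAAGAGAGAGAGCAC	21	94	3512	3	317	3926
156	ath-miR156a	UGACAGAAGAGAGUGAGCAC	20	82529	63	3705	14478	100775
156	ath-miR156g	CGACAGAAGAGAGUGAGCAC	20	74	0	3	10	87
156	bna-miR156a	UGACAGAAGAGAGUGAGCACA	21	112	21	2	26	161
156	ptc-miR156k	UGACAGAAGAGAGGGAGCAC	20	47	0	6	2	55
156	vvi-miR156e	UGACAGAGGAGAGUGAGCAC	20	30	0	1	1	32
156	zma-miR156k	UGACAGAAGAGAGCGAGCAC	20	183	0	14	10	207
157	ath-miR157a	UUGACAGAAGAUAGAGAGCAC	21	3114	2787	4370	4839	15110
157	ath-miR157d	UGACAGAAGAUAGAGAGCAC	20	361	30	26	89	506
159	aqc-miR159	UUUGGACUGAAGGGAGCUCUA	21	33	312	43	89	477
159	pvu-miR159a.1	UUUGGAUUGAAGGGAGCUCUA	21	67007	1082688	180739	453692	1784126
159	ath-miR159b	UUUGGAUUGAAGGGAGCUCUU	21	3	438	135	178	754
159	gma-miR159c	AUUGGAGUGAAGGGAGCUCCG	21	0	0	1044	25	1069
159	gma-miR159d	AGCUGCUUAGCUAUGGAUCCC	21	78	148	202	240	668
159	osa-miR159a.1	UUUGGAUUGAAGGGAGCUCUG	21	37	224	31	148	440
159	osa-miR159f	CUUGGAUUGAAGGGAGCUCUA	21	57	666	298	182	1203
159	pta-miR159a	UUGGAUUGAAGGGAGCUCCA	20	0	3	0	25	28
160	ath-miR160a	UGCCUGGCUCCCUGUAUGCCA	21	136	5160	5474	104	10874
160	bdi-miR160	UGCCUGGCUCCCUGUAUGCC	20	9	212	225	5	451
160	osa-miR160f	UGCCUGGCUCCCUGAAUGCCA	21	9	3	240	2	254
162	ath-miR162a	UCGAUAAACCUCUGCAUCCAG	21	597	583	517	1192	2889
162	zma-miR162	UCGAUAAACCUCUGCAUCCA	20	14	22	15	30	81
164	ath-miR164a	UGGAGAAGCAGGGCACGUGCA	21	7245	5621	3628	1229	17723
164	ath-miR164c	UGGAGAAGCAGGGCACGUGCG	21	49	71	91	122	333
166	gma-miR166a	UCGGACCAGGCUUCAUUCCCC	21	5333	53276	20481	15163	94253
166	ctr-miR166	UCGGACCAGGCUUCAUUCCCCC	22	2	18	10	10	40
166	osa-miR166e	UCGAACCAGGCUUCAUUCCCC	21	0	17	8	4	29
166	vvi-miR166a	UCGGACCAGGCUUCAUUCC	19	93	205	166	382	846
166	zma-miR166h	UCGGACCAGGCUUCAUUCCC	20	140	769	352	630	1891
167	ath-miR167a	UGAAGCUGCCAGCAUGAUCUA	21	661	2883	3251	90	6885
167	ath-miR167d	UGAAGCUGCCAGCAUGAUCUGG	22	22003	1443	5196	626	29268
167	bna-miR167a	UGAAGCUGCCAGCAUGAUCUAA	22	2	0	17	0	19
167	ccl-miR167a	UGAAGCUGCCAGCAUGAUCUGA	22	2267	8164	2727	276	13434
167	osa-miR167d	UGAAGCUGCCAGCAUGAUCUG	21	15021	20039	6209	378	41647
167	ptc-miR167f	UGAAGCUGCCAGCAUGAUCUU	21	36	252	146	5	439
168	ath-miR168a	UCGCUUGGUGCAGGUCGGGAA	21	382	991	605	43	2021
169	ath-miR169a	CAGCCAAGGAUGACUUGCCGA	21	0	11	0	44	55
169	ath-miR169b	CAGCCAAGGAUGACUUGCCGG	21	1339	8784	154	6351	16628
169	gma-miR169d	UGAGCCAAGGAUGACUUGCCGGU	23	0	4	11	0	15
169	gma-miR169e	AGCCAAGGAUGACUUGCCGG	20	133	47	62	316	558
169	mtr-miR169c	CAGCCAAGGGUGAUUUGCCGG	21	3916	166	78	2	4162
169	mtr-miR169d	AAGCCAAGGAUGACUUGCCGG	21	126	863	389	4	1382
169	osa-miR169e	UAGCCAAGGAUGACUUGCCGG	21	1	29	1	16	47
171	ath-miR171b	UUGAGCCGUGCCAAUAUCACG	21	119	790	0	37	946
171	sly-miR171d	UUGAGCCGCGCCAAUAUCAC	20	2	1	67	7	77
171	zma-miR171b	UUGAGCCGUGCCAAUAUCAC	20	28	40	13	2	83
171	zma-miR171f	UUGAGCCGUGCCAAUAUCACA	21	62	245	139	68	514
172	ath-miR172a	AGAAUCUUGAUGAUGCUGCAU	21	43	38	24	1	106
172	ptc-miR172g	GGAAUCUUGAUGAUGCUGCAG	21	353	18985	200	51	19589
172	sbi-miR172b	GGAAUCUUGAUGAUGCUGCA	20	1	193	7	0	201
172	zma-miR172a	AGAAUCUUGAUGAUGCUGCA	20	344	565	622	36	1567
319	ath-miR319a	UUGGACUGAAGGGAGCUCCCU	21	0	1672	192	320	2184
319	mtr-miR319	UUGGACUGAAGGGAGCUCCC	20	21	66392	4936	40730	112079
319	osa-miR319a	UUGGACUGAAGGGUGCUCCC	20	0	19	5	3	27
319	ppt-miR319a	CUUGGACUGAAGGGAGCUCC	20	1	1622	14	106	1743
319	ppt-miR319c	CUUGGACUGAAGGGAGCUCCC	21	16	11934	643	3082	15675
319	pta-miR319	UUGGACUGAAGGGAGCUCC	19	0	1917	201	1139	3257
319	ptc-miR319e	UUGGACUGAAGGGAGCUCCU	20	0	22	58	45	125
319	vvi-miR319e	UUUGGACUGAAGGGAGCUCCU	21	0	55	2	1	58
319	vvi-miR319g	UUGGACUGAAGGGAGCUCCCA	21	0	285	23	53	361
390	ath-miR390a	AAGCUCAGGAGGGAUAGCGCC	21	299	1264	153	63	1779
390	gma-miR390b	AAGCUCAGGAGGGAUAGCACC	21	46	25	193	124	388
393	ath-miR393a	UCCAAAGGGAUCGCAUUGAUCC	22	51	295	441	9	796
393	osa-miR393	UCCAAAGGGAUCGCAUUGAUC	21	13	65	101	0	179
394	ath-miR394a	UUGGCAUUCUGUCCACCUCC	20	71	7473	339	482	8365
394	vvi-miR394a	UUGGCAUUCUGUCCACCUCCAU	22	0	112	7	0	119
395	tae-miR395b	UGAAGUGUUUGGGGGAACUC	20	5	25	4	8	42
396	ath-miR396a	UUCCACAGCUUUCUUGAACUG	21	760	44655	10489	601	56505
396	ath-miR396b	UUCCACAGCUUUCUUGAACUU	21	1	185	33	16	235
396	gma-miR396d	AAGAAAGCUGUGGGAGAAUAUGGC	24	0	61	22	77	160
396	gma-miR396e	UUCCACAGCUUUCUUGAACUGU	22	0	29	6	0	35
396	ptc-miR396f	UUCCACGGCUUUCUUGAACUG	21	0	11	4	1	16
396	vvi-miR396a	UUCCACAGCUUUCUUGAACUA	21	0	23	2	1	26
396	vvi-miR396b	UUCCACAGCUUUCUUGAACU	20	742	19924	2108	823	23597
397	ath-miR397a	UCAUUGAGUGCAGCGUUGAUG	21	2057	13	5276	70	7416
397	zma-miR397a	UCAUUGAGCGCAGCGUUGAUG	21	5	0	23	0	28
398	ahy-miR398	UGUGUUCUCAGGUCACCCCU	20	0	25	350	0	375
398	osa-miR398b	UGUGUUCUCAGGUCGCCCCUG	21	3760	57	1717	7	5541
399	ath-miR399a	UGCCAAAGGAGAUUUGCCCUG	21	15	12	4	0	31
399	ath-miR399b	UGCCAAAGGAGAGUUGCCCUG	21	35	121	22	2	180
399	osa-miR399e	UGCCAAAGGAGAUUUGCCCAG	21	49	45	3	1	98
408	ath-miR408	AUGCACUGCCUCUUCCCUGGC	21	2083	3718	9050	167	15018
408	bdi-miR408	AUGCACUGCCUCUUCCCUGG	20	5	25	67	0	97
408	osa-miR408	CUGCACUGCCUCUUCCCUGGC	21	3	5	17	0	25
408	ppt-miR408b	UGCACUGCCUCUUCCCUGGCU	21	0	5	55	0	60
482	gso-miR482a	UCUUCCCUACACCUCCCAUAC	21	7	318	85	2	412
482	pvu-miR482	UCUUCCCAAUUCCGCCCAUUCC	22	5	291	54	0	350
1511	gma-miR1511	AACCAGGCUCUGAUACCAUG	20	978	625	449	1529	3581
1514	pvu-miR1514a	UUCAUUUUGAAAAUAGGCAUUG	22	188	5481	1282	311	7262
1515	gma-miR1515	UCAUUUUGCGUGCAAUGAUCUG	22	27	853	341	86	1307
2111	ath-miR2111a	UAAUCUGCAUCCUGAGGUUUA	21	48	211	255	0	514
2118	mtr-miR2118	UUACCGAUUCCACCCAUUCCUA	22	8	7	1	1	17
2118	pvu-miR2118	UUGCCGAUUCCACCCAUUCCUA	22	238	17300	13707	1771	33016
2119	gma-miR2119	UCAAAGGGAGUUGUAGGGGAA	21	85	42	1448	6	1581
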