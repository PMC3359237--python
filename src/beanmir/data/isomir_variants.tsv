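group	role	name	sequence	length	LL	FL	RL	SL	total
length	reference	gma-miR1511	AACCAGGCTCTGATACCATG	20	978	625	449	1529	3581
length	variant	pvu-isomiR1511	AACCAGGCTCTGATACCATGA	21	14902	13725	7707	17239	53573
length	reference	gso-miR482a	TCTTCCCTACACCTCCCATAC	21	7	318	85	2	412
length	variant	pvu-isomiR482a	TCTTCCCTACACCTCCCATACC	22	369	17616	5564	305	23854
length	reference	mtr-miR171c	TGATTGAGCCGTGCCAATATT	21	0	0	0	0	0
length	variant	pvu-isomiR171a	TGATTGAGCCGTGCCAATA	19	115	1390	60	57	1622
length	reference	pvu-miR482*	GGAATGGGCTGATTGGGAAGCA	22	1185	6	440	10	1641
length	variant	pvu-isomiR482*	GGAATGGGCTGATTGGGAAGC	21	714044	3806	173153	1	1207244
length	reference	pvu-miR159a.2	CTTCCATATCTGGGGAGCTTC	21	1	0	0	0	1
length	variant	pvu-isomiR159a	CTTCCATATCTGGGGAGCT	19	13	263	157	23	456
length	reference	gma-miR4376	TACGCAGGAGAGATGACGCTGT	22	1	1	0	0	2
length	variant	pvu-isomiR4376	TACGCAGGAGAGATGACGCTG	21	3841	1090	0	398	5329
length	reference	mtr-miR171b	TGATTGAGCCGCGTCAATATC	21	0	0	0	0	0
length	variant	pvu-isomiR171b	TCTGATTGAGCCGCGTCAATA	21	101	1	79	10	191
non_conserved	reference	ath-miR858	TTTCGTTGTCTGTTCGACCTT	21	0	0	0	0	0
non_conserved	variant	pvu-isomiR858	CTCGTTGTCTGTTCGACCTTG	21	37	351	0	26	414
non_conserved	reference	csi-miR479	TGTGATATTGGTTCGGCTCATC	22	0	0	0	0	0
non_conserved	variant	pvu-isomiR479	TGTGATATTGGTTTGGCTCA	20	58	1	1588	11	1658
non_conserved	reference	gma-miR1510a-3p	TTGTTGTTTTACCTATTCCACC	22	0	0	0	0	0
non_conserved	variant	pvu-isomiR1510a	TGTTGTTTTTCCTATTCCACC	21	463	877	902	28	2270
non_conserved	reference	gma-miR1510b	TGTTGTTTTACCTATTCCACC	21	0	0	4	0	4
non_conserved	variant	pvu-isomiR1510b	TTGTTTTTCCTATTCCACCAA	21	3313	17893	8413	222	29841
non_conserved	reference	mtr-miR2199	TGATACACTAGCACGGATCAC	21	8	0	0	0	8
non_conserved	variant	pvu-isomiR2199a	TGATACACTAGCACGGGTCAC	21	16	1323	799	59	2197
non_conserved	reference	mtr-miR2199	TGATACACTAGCACGGATCAC	21	8	0	0	0	8
non_conserved	variant	pvu-isomiR2199b	TGATACACTAGTACGGATCAC	21	2586	0	0	5	2591
non_conserved	reference	mtr-miR2597	TTTGGTACTTCGTCGATTTGA	21	0	0	0	0	0
non_conserved	variant	pvu-isomiR2597	TTTGGTACTTCCTTGATTTGA	21	0	22	253	0	275
non_conserved	reference	ppt-miR894	CGTTTCACGTCGGGTTCACC	20	1	3	1	0	5
non_conserved	variant	pvu-isomiR894	CGTTTCACGTCAGGTTCACCA	21	15	6	0	0	21
non_conserved	reference	pta-miR1310	GGCATCGGGGGCGTAACGCCCCT	23	0	0	0	0	0
non_conserved	variant	pvu-isomiR1310	GGCATCGGGGGCGCAACGCCC	21	33	5	0	0	38
conserved	reference	ctr-miR166a	TCGGACCAGGCTTCATTCCCCC	22	2	18	10	10	40
conserved	variant	pvu-isomiR166a	TCGGACCAGGCTTCCTTCCCC	21	113	371	241	63	788
conserved	reference	osa-miR156l	CGACAGAAGAGAGTGAGCATA	21	0	0	0	0	0
conserved	variant	pvu-isomiR156a	TGACAGAAGAGAGTGAGCA	19	2682	7	334	222	3245
conserved	reference	mtr-miR164d	TGGAGAAGCAGGGCACATGCT	21	0	0	0	0	0
conserved	variant	pvu-isomiR164a	TGGAGAAGCAGGACACATGC	20	58	64	535	12	669
conserved	reference	vvi-miR156e	TGACAGAGGAGAGTGAGCAC	20	30	0	1	1	32
conserved	variant	pvu-isomiR156b	TGACAGACGAGAGTGAGCAC	20	261	0	2	2	265
conserved	reference	csi-miR393	ATCCAAAGGGATCGCATTGATC	22	1	0	0	0	1
conserved	variant	pvu-isomiR393	TTCCAAAGGGATCGCATTGA	20	911	581	667	4	2163
conserved	reference	ctr-miR171	TTGAGCCGCGTCAATATCTCC	21	0	0	0	0	0
conserved	variant	pvu-isomiR171c	TTGAGCCGCGTCAATATCTCA	21	30	151	129	58	368
conserved	reference	mtr-miR169p	TGAGCCAGGATGGCTTGCCGG	21	0	0	0	0	0
conserved	variant	pvu-isomiR169a	TGAGCCGGGATGGCTTGCCGG	21	2	228	26	97	353
conserved	reference	ptc-miR396f	TTCCACGGCTTTCTTGAACTG	21	0	11	4	1	16
conserved	variant	pvu-isomiR396a	TTCCACCGCTTTCTTGAACTG	21	11	10	3	0	24
conserved	reference	zma-miR398a	TGTGTTCTCAGGTCGCCCCCG	21	2	0	2	0	4
conserved	variant	pvu-isomiR398a	TGTGTTCTCAGGCCGCCCCTG	21	21	0	18	0	39
conserved	reference	sly-miR171c	TATTGGTGCGGTTCAATGAGA	21	0	0	0	0	0
conserved	variant	pvu-isomiR171d	TATTGGTCCGGTTCAATGAGA	21	353	386	0	192	931
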