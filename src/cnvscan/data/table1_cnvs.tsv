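entry	locus	chrom	gene	sample_id	cnv_type	start	end	size	furthest_distance	bin
1	2p16.3	2	NRXN1	1-0045-004	loss	51405882	51524684	118802	1124	ii
1	2p16.3	2	NRXN1	8-3394-003	loss	51439897	51479683	39786	1124	ii
1	2p16.3	2	NRXN1	8-3394-003	loss	51157414	51189362	31948	1124	ii
1	2p16.3	2	NRXN1	8-14144-2420	loss	51157414	51225851	68437	1124	ii
1	2p16.3	2	NRXN1	1-0496-003	gain	52220120	52238172	18052	1124	ii
1	2p16.3	2	NRXN1	1-0449-003	loss	52237072	52253660	16588	1124	ii
2	3p22.3	3	ARPP21	2-1213-003	loss	34984049	35102773	118724	563	ii
2	3p22.3	3	ARPP21	3-0100-000	gain	35086691	35094736	8045	563	ii
3	3q24	3	C3orf58;ZIC1;ZIC4	1-0007-003	loss	146168760	146934953	766193	1383;1955;1979	i
3	3q24	3	C3orf58;ZIC1;ZIC4	8-3093-004	loss	146575437	146631141	55704	1383;1955;1979	i
4	4q13.1	4	EPHA5	8-14208-3350	loss	66505324	66633530	128206	840	i
4	4q13.1	4	EPHA5	8-14186-3050	loss	66515708	66633530	117822	840	i
4	4q13.1	4	EPHA5	1-0138-004	loss	66515708	66633530	117822	840	i
4	4q13.1	4	EPHA5	2-0082-004	loss	67045815	67134170	88355	840	i
4	4q13.1	4	EPHA5	1-0455-003	loss	67058506	67075558	17052	840	i
5	6p21.2	6	MOCS1	3-0139-000	gain	40021898	40078515	56617	168	i or ii
5	6p21.2	6	MOCS1	2-0139-003	gain	40023327	40062155	38828	168	i or ii
5	6p21.2	6	MOCS1	1-0381-003	loss	40174188	40209324	35136	168	i or ii
5	6p21.2	6	MOCS1	2-1368-003	loss	40174188	40210694	36506	168	i or ii
6	7q21.11	7	SEMA3C	8-6258-03	loss	80431202	80512022	80820	96	i
6	7q21.11	7	SEMA3C	1-0345-005	loss	80482597	80517630	35033	96	i
7	8p12	8	UNC5D;NRG1	8-14243-3670	loss	34923482	34956067	32585	256;2183	i
7	8p12	8	UNC5D;NRG1	3-0044-000	loss	34923482	34956067	32585	256;2183	i
7	8p12	8	UNC5D;NRG1	3-0300-000	loss	34925149	34957854	32705	256;2183	i
7	8p12	8	UNC5D;NRG1	8-14181-2940	loss	34923482	34956067	32585	256;2183	i
8	8q24.13	8	ZHX2	8-3317-003	gain	123572785	123625681	52896	237	i or ii
8	8q24.13	8	ZHX2	3-0186-000	loss	123583028	123639417	56389	237	i or ii
9	9q33.1	9	ASTN2	8-3055-004	loss	119254497	119374796	120299	98	i
9	9q33.1	9	ASTN2	3-0115-000	loss	119314967	119319559	4592	98	i
10	9q34.2	9	OLFM1;RXRA	2-1272-003	gain	136479329	136604233	124904	508;8	i
10	9q34.2	9	OLFM1;RXRA	2-1189-003	gain	136480334	136598491	118157	508;8	i
11	11p14.3	11	LUZP2	8-14175-2820	loss	24177612	24316053	138441	160	i or ii
11	11p14.3	11	LUZP2	8-14059-1020	loss	24262511	24303132	40621	160	i or ii
11	11p14.3	11	LUZP2	8-14208-3350	loss	24262511	24303132	40621	160	i or ii
12	11p12	11	LRRC4C	8-14208-3350	gain	40304880	40703298	398418	196	iii
12	11p12	11	LRRC4C	2-0272-003	loss	40379668	40550356	170688	196	iii
12	11p12	11	LRRC4C	SK0167-003	loss	40417554	40610400	192846	196	iii
12	11p12	11	LRRC4C	3-0208-000	loss	40468058	40492541	24483	196	iii
13	11p12	11	LRRC4C	8-14032-600	loss	41990280	42021250	30970	1738	i or ii
13	11p12	11	LRRC4C	8-3276-003	loss	42243624	42279094	35470	1738	i or ii
13	11p12	11	LRRC4C	2-0286-003	loss	42243624	42279094	35470	1738	i or ii
14	11q13.2	11	MRGPRD	4-0023-003	loss	68486121	68493638	7517	10	i
14	11q13.2	11	MRGPRD	2-1075-003	loss	68486121	68500238	14117	10	i
15	16q21	16	CDH8	8-14251-3750	loss	61650435	61787984	137549	1030	i or ii
15	16q21	16	CDH8	2-1175-003	loss	61658675	61755232	96557	1030	i or ii
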