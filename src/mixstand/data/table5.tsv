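equation	group	variables	n	a0	sd_a0	p_a0	a1	sd_a1	p_a1	a2	sd_a2	p_a2	a3	sd_a3	p_a3
4.1	N. sp., E. be.	IMc~ dq, m	20755	1.6273	0.1079	<0.001	-0.0290	0.0329	<0.3781	0.8599	0.1449	<0.001	-0.2149	0.0439	<0.001
4.2	N. sp., s. fir, E. be.	IMc~ dq, m	1521	1.9347	0.1166	<0.001	-0.1148	0.0420	<0.001	0.2645	0.0683	<0.001
4.2	N. sp., S. pi.	IMc~ dq, m	12256	2.6578	0.0905	<0.001	-0.5624	0.0296	<0.001	0.3609	0.0230	<0.001
4.2	S. pi., E. be.	IMc~ dq, m	11517	1.7428	0.0778	<0.001	-0.0865	0.0255	<0.001	0.1402	0.0196	<0.001
4.1	S. oak, E. be.	IMc~ dq, m	24824	2.3473	0.0349	<0.001	-0.4570	0.0117	<0.001	-0.4104	0.0602	<0.001	0.2054	0.0197	<0.001
4.2	E. ash, syc. map.	IMc~ dq, m	3279	1.7640	0.1522	<0.001	-0.1489	0.0491	<0.001	0.4270	0.0420	<0.001
5	N. sp., E. be.	id~ dqc, dq, m	16611	-2.2701	0.0891	<0.001	0.1813	0.0266	<0.001	0.05827	0.0156	<0.001
5	N. sp., s. fir, E. be.	id~dqc, dq, m	1420	-1.2868	0.1306	<0.001	0.0819	0.0467	<0.001	0.0068	0.0751	<0.001
5	N. sp., S. pi.	id~dqc, dq, m	9398	-2.5987	0.0928	<0.001	0.0968	0.0296	<0.001	0.1679	0.0244	<0.001
5	S. pi., E. be.	id~dqc, dq, m	9617	-2.2357	0.0913	<0.001	0.1263	0.0296	<0.001	0.0955	0.0214	<0.001
5	S. oak, E. be	id~dqc, dq, m	20205	-2.3588	0.0442	<0.001	0.0880	0.0145	<0.001	0.2052	0.0140	<0.001
5	E. ash, syc. map.	id~dqc, dq, m	2731	-3.9440	0.1718	<0.001	0.6937	0.0543	<0.001	0.2684	0.0442	<0.001
6	N. sp., E. be.	LAIc~dqc, dq, m	20755	0.9845	0.0294	<0.001	1.1332	0.0180	<0.001	-0.6494	0.0200	<0.001	0.0471	0.0052	<0.001
6	N. sp., s. fir, E. be.	LAIc~dqc, dq, m	1521	0.2393	0.0642	<0.001	0.6562	0.0227	<0.001	0.1599	0.0352	<0.001
6	N. sp., S. pi.	LAIc~dqc, dq, m	12256	0.9290	0.0272	<0.001	1.5342	0.0168	<0.001	-1.3499	0.0176	<0.001	0.0820	0.0072	<0.001
6	S. pi., E. be.	LAIc~dqc, dq, m	11517	-1.4635	0.0311	<0.001	1.5742	0.0191	<0.001	-0.5711	0.0196	<0.001	0.0329	0.0065	<0.001
6	S. oak, E. be	LAIc~dqc, dq, m	24824	1.2427	0.0160	<0.001	1.2016	0.0105	<0.001	-0.8581	0.0102	<0.001	0.3050	0.0048	<0.001
6	E. ash, syc. map.	LAIc~dqc, dq, m	3279	-0.8704	0.0627	<0.001	2.0059	0.0364	<0.001	-0.7368	0.0338	<0.001	0.0729	0.0167	<0.001
7	N. sp., E. be.	IMc~LAIc, m	20755	-1.2060	0.0470	<0.001	1.1026	0.0182	<0.001	0.0497	0.0155	<0.001
7	N. sp., s. fir, E. be.	IMc~LAIc, m	1521	0.2407	0.0739	<0.001	0.6973	0.0352	<0.001	-0.0497	0.0565	<0.379
7	N. sp., S. pi.	IMc~LAIc, m	12256	0.7381	0.0280	<0.001	1.5081	0.0189	<0.001	0.0025	0.0196	<0.001
7	S. pi., E. be.	IMc~LAIc, m	11517	0.4374	0.0249	<0.001	0.8446	0.0170	<0.001	0.0834	0.0171	<0.001
7	S. oak, E. be	IMc~LAIc, m	24824	-1.0045	0.0166	<0.001	0.9444	0.0073	<0.001	-0.1282	0.0072	<0.001
7	E. ash, syc. map.	IMc~LAIc, m	3279	-0.8101	0.0714	<0.001	0.8759	0.0280	<0.001	0.2702	0.0356	<0.001
8	N. sp., (E. be.)	id~d, SDIci, m	9936	-2.7460	0.1686	<0.001	0.7589	0.0254	<0.001	-0.1869	0.0213	<0.001	0.0114	0.0195	<0.560
8	(N. sp.), E. be.	id~d, SDIci, m	6206	-3.7709	0.1780	<0.001	0.9980	0.0296	<0.001	-0.1652	0.0217	<0.001	0.0464	0.0242	<0.050
8	N. sp., (s. fir, E. be.)	id~d, SDIci, m	1123	-0.8046	0.2092	<0.001	0.4199	0.0422	<0.001	-0.2185	0.0298	<0.001	-0.0975	0.0884	<0.270
8	N. sp., s. fir, E. be.	id~d, SDIci, m	206	-2.5526	0.7979	<0.001	0.5208	0.1487	<0.001	-0.0689	0.0843	<0.415	-0.0500	0.1575	<0.751
8	N. sp., S. pi.	id~d, SDIci, m	3576	-4.8825	0.3307	<0.001	0.5192	0.0397	<0.001	0.2007	0.0418	<0.001	0.0611	0.0537	<0.226
8	N. sp., S. pi.	id~d, SDIci, m	5788	-4.5425	0.1751	<0.001	1.3464	0.0290	<0.001	-0.2142	0.0231	<0.001	0.0658	0.0296	<0.027
8	S. pi., E. be.	id~d, SDIci, m	3762	-1.2316	0.2196	<0.001	0.5162	0.0373	<0.001	-0.2860	0.0297	<0.001	0.0966	0.0337	<0.004
8	S. pi., E. be.	id~d, SDIci, m	3554	-2.9990	0.2011	<0.001	1.0253	0.0367	<0.001	-0.2582	0.0269	<0.001	0.1260	0.0332	<0.001
8	S. oak, E. be	id~d, SDIci, m	8173	-1.9319	0.1628	<0.001	0.5833	0.0178	<0.001	-0.2219	0.0214	<0.001	-0.2037	0.0235	<0.001
8	s. oak, E. be	id~d, SDIci, m	11098	-5.0467	0.0907	<0.001	1.0927	0.0144	<0.001	-0.0258	0.0125	<0.038	0.1740	0.0157	<0.001
8	E. ash, syc. map.	id~d, SDIci, m	709	-3.6485	0.3790	<0.001	1.1182	0.0564	<0.001	-0.1739	0.0572	<0.002	0.1322	0.0594	<0.027
8	E. ash, syc. map.	id~d, SDIci, m	1290	-5.7095	0.4062	<0.001	1.5194	0.0483	<0.001	-0.0388	0.0576	<0.500	0.0398	0.0582	<0.495
9	N. sp., E. be.	id~SDIc, m	16611	-0.5153	0.1078	<0.001	-0.1690	0.0156	<0.001	0.0920	0.0158	<0.001
9	N. sp., s. fir, E. be.	id~SDIc, m	1420	-0.0578	0.1772	<0.001	-0.1663	0.0287	<0.001	0.1294	0.0722	<0.071
9	N. sp., S. pi.	id~SDIc, m	9398	-1.2340	0.1392	<0.001	-0.1618	0.0202	<0.001	0.2209	0.0254	<0.001
9	S. pi., E. be.	id~SDIc, m	9617	-0.2529	0.1213	<0.037	-0.2440	0.0182	<0.001	0.1463	0.0215	<0.001
9	S. oak, E. be.	id~SDIc, m	20205	-0.9649	0.0744	<0.001	-0.1832	0.0117	<0.001	0.2492	0.0138	<0.001
9	E. ash, syc. map.	id~SDIc, m	2731	-0.8018	0.2556	<0.002	-0.1615	0.0411	<0.001	0.2705	0.0460	<0.001
10	N. sp., E. be.	IM~SDIc, m	20755	-3.1854	0.1057	<0.001	0.6883	0.0153	<0.001	0.0563	0.0160	<0.001
10	N. sp., s. fir, E. be.	IM~SDIc, m	1521	-1.0519	0.1391	<0.001	0.4409	0.0225	<0.001	0.0329	0.0565	<0.561
10	N. sp., S. pi.	IM~SDIc, m	12256	-5.0963	0.1268	<0.001	0.9000	0.0187	<0.001	0.0788	0.0227	<0.001
10	S. pi., E. be.	IM~SDIc, m	11517	-2.2157	0.1041	<0.001	0.5567	0.0156	<0.001	0.0703	0.0182	<0.001
10	S. oak, E. be.	IM~SDIc, m	24824	-3.6260	0.0353	<0.001	0.7481	0.0056	<0.001	0.0251	0.0069	<0.001
10	E. ash, syc. map.	IM~SDIc, m	3279	-4.2795	0.2086	<0.001	0.8999	0.0334	<0.001	0.3350	0.0369	<0.001
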