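# Synthetic 25-state structural alphabet (4 Ca points per state, angstrom).
# Stand-in with the canonical schema/cardinality; not the published M32K25 coordinates.
state	point	x	y	z
1	1	4.5485	1.6693	-1.7783
1	2	0.7644	1.4871	-1.4838
1	3	-1.0698	-0.7974	0.9363
1	4	-4.2431	-2.3591	2.3259
2	1	-2.0564	0.1873	2.7686
2	2	-2.8159	-1.4015	-0.5987
2	3	0.8253	-0.3982	-1.0170
2	4	4.0470	1.6124	-1.1529
3	1	1.3822	-4.7923	1.6436
3	2	1.3643	-1.1073	0.7162
3	3	-0.4869	1.3118	-1.5557
3	4	-2.2596	4.5878	-0.8041
4	1	-2.7651	-4.2515	1.7978
4	2	-1.3774	-1.5028	-0.4292
4	3	0.7296	1.5916	-1.0811
4	4	3.4129	4.1626	-0.2875
5	1	0.0703	1.0261	4.7398
5	2	2.0033	0.2465	1.5624
5	3	-0.1924	-0.4535	-1.4590
5	4	-1.8813	-0.8191	-4.8433
6	1	-1.7078	0.3116	1.9822
6	2	-0.3887	3.4324	0.2616
6	3	0.5635	-0.0436	-0.9427
6	4	1.5329	-3.7004	-1.3011
7	1	-2.5465	-0.8253	4.5054
7	2	0.0848	-0.8903	1.7646
7	3	1.6192	-0.2699	-1.6560
7	4	0.8424	1.9855	-4.6140
8	1	0.4421	1.1766	5.2918
8	2	-0.0141	-0.0959	1.7404
8	3	0.3682	-1.2598	-1.8567
8	4	-0.7962	0.1792	-5.1754
9	1	1.5457	-1.1091	0.2541
9	2	2.1895	1.9928	-1.8444
9	3	-1.0253	0.2936	-0.7410
9	4	-2.7099	-1.1773	2.3313
10	1	5.2565	-0.7140	-1.6084
10	2	1.8758	0.2087	-0.1389
10	3	-1.8994	-0.1728	0.0668
10	4	-5.2328	0.6782	1.6805
11	1	-2.7605	0.3821	-2.6361
11	2	-0.0102	-1.0084	-0.4129
11	3	2.3331	-0.9525	2.5781
11	4	0.4376	1.5788	0.4710
12	1	3.3549	1.9053	3.2543
12	2	0.8352	-0.3882	1.5717
12	3	-0.6029	-1.6906	-1.6956
12	4	-3.5872	0.1735	-3.1304
13	1	3.4596	-0.8632	-1.7263
13	2	1.5478	2.2731	-0.7522
13	3	-0.9100	0.3188	1.3879
13	4	-4.0974	-1.7287	1.0906
14	1	3.1504	-2.4411	1.3302
14	2	-0.1450	-1.0329	0.0664
14	3	0.0712	2.7391	-0.3399
14	4	-3.0767	0.7349	-1.0567
15	1	1.4615	5.0633	1.0482
15	2	-0.3075	1.7119	1.3291
15	3	-0.5587	-1.6404	-0.4426
15	4	-0.5953	-5.1349	-1.9348
16	1	-2.2575	3.2507	2.6050
16	2	-1.7737	-0.0671	0.8166
16	3	0.5785	-2.5197	-0.8839
16	4	3.4527	-0.6640	-2.5377
17	1	3.8856	1.8250	0.4799
17	2	0.1987	2.7449	0.4602
17	3	-1.5527	-0.4542	-0.6068
17	4	-2.5315	-4.1157	-0.3333
18	1	3.0396	-3.9705	-0.4125
18	2	0.0535	-1.9366	0.7650
18	3	-1.9374	1.2988	0.6717
18	4	-1.1556	4.6083	-1.0242
19	1	2.5928	2.7399	-1.5382
19	2	-0.8528	1.2357	-2.0902
19	3	-2.0387	-1.2920	0.4875
19	4	0.2987	-2.6835	3.1408
20	1	-0.0649	-3.3079	-3.4631
20	2	0.3776	-1.2464	-0.3017
20	3	1.2671	2.3299	0.6251
20	4	-1.5799	2.2244	3.1398
21	1	-2.2062	-0.0043	3.4622
21	2	-0.8282	1.4235	0.2214
21	3	-0.0921	-0.6872	-2.8516
21	4	3.1265	-0.7319	-0.8320
22	1	0.4951	1.1362	-4.3041
22	2	1.0574	2.0563	-0.6603
22	3	-0.9739	-0.8257	0.7568
22	4	-0.5786	-2.3669	4.2077
23	1	0.7916	-3.3689	-4.1556
23	2	1.3155	-0.7880	-1.4161
23	3	-0.4708	1.4340	1.0962
23	4	-1.6363	2.7230	4.4755
24	1	2.5984	-3.6316	1.9399
24	2	0.2690	-2.2447	-0.7228
24	3	-1.3574	1.1234	-0.0511
24	4	-1.5101	4.7529	-1.1660
25	1	-1.9278	0.9776	5.1504
25	2	0.0027	0.2110	1.9684
25	3	0.6897	-0.0484	-1.7600
25	4	1.2355	-1.1401	-5.3587
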