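node_a	node_b	weight
0	1	4
0	2	5
0	3	3
0	4	3
0	5	3
0	6	3
0	7	2
0	8	2
0	10	2
0	11	3
0	12	1
0	13	3
0	17	2
0	19	2
0	21	2
0	31	2
1	2	6
1	3	3
1	7	4
1	13	5
1	17	1
1	19	2
1	21	2
1	30	2
2	3	3
2	7	4
2	8	5
2	9	1
2	13	3
2	27	2
2	28	2
2	32	2
3	7	3
3	12	3
3	13	3
4	6	2
4	10	3
5	6	5
5	10	3
5	16	3
6	16	3
8	30	3
8	32	3
8	33	4
9	33	2
13	33	3
14	32	3
14	33	2
15	32	3
15	33	4
18	32	1
18	33	2
19	33	1
20	32	3
20	33	1
22	32	2
22	33	3
23	25	5
23	27	4
23	29	3
23	32	5
23	33	4
24	25	2
24	27	3
24	31	2
25	31	7
26	29	4
26	33	2
27	33	4
28	31	2
28	33	2
29	32	4
29	33	2
30	32	3
30	33	3
31	32	4
31	33	4
32	33	5
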