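node_a	node_b	weight
0	1	1
0	2	1
0	3	1
0	4	1
0	5	1
0	6	1
0	7	1
0	8	1
0	10	1
0	11	1
0	12	1
0	13	1
0	17	1
0	19	1
0	21	1
0	31	1
1	2	1
1	3	1
1	7	1
1	13	1
1	17	1
1	19	1
1	21	1
1	30	1
2	3	1
2	7	1
2	8	1
2	9	1
2	13	1
2	27	1
2	28	1
2	32	1
3	7	1
3	12	1
3	13	1
4	6	1
4	10	1
5	6	1
5	10	1
5	16	1
6	16	1
8	30	1
8	32	1
8	33	1
9	33	1
13	33	1
14	32	1
14	33	1
15	32	1
15	33	1
18	32	1
18	33	1
19	33	1
20	32	1
20	33	1
22	32	1
22	33	1
23	25	1
23	27	1
23	29	1
23	32	1
23	33	1
24	25	1
24	27	1
24	31	1
25	31	1
26	29	1
26	33	1
27	33	1
28	31	1
28	33	1
29	32	1
29	33	1
30	32	1
30	33	1
31	32	1
31	33	1
32	33	1
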