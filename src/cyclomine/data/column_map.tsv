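column	consensus_position
0	-76
1	-75
2	-74
3	-73
4	-72
5	-71
6	-70
7	-69
8	-68
9	-67
10	-66
11	-65
12	-64
13	-63
14	-62
15	-61
16	-60
17	-59
18	-58
19	-57
20	-56
21	-55
22	-54
23	-53
24	-52
25	-51
26	-50
27	-49
28	-48
29	-47
30	-46
31	-45
32	-44
33	-43
34	-42
35	-41
36	-40
37	-39
38	-38
39	-37
40	-36
41	-35
42	-34
43	-33
44	-32
45	-31
46	-30
47	-29
48	-28
49	-27
50	-26
51	-25
52	-24
53	-23
54	-22
55	-21
56	-20
57	-19
58	-18
59	-17
60	-16
61	-15
62	-14
63	-13
64	-12
65	-11
66	-10
67	-9
68	-8
69	-7
70	-6
71	-5
72	-4
73	-3
74	-2
75	-1
76	0
77	1
78	2
79	3
80	4
81	5
82	6
83	7
84	8
85	9
86	10
87	11
88	12
89	13
90	14
91	15
92	16
93	17
94	18
95	19
96	20
97	21
98	22
99	23
100	24
101	25
102	26
103	27
104	28
105	29
106	30
107	31
108	32
109	33
110	34
111	35
112	36
113	37
114	38
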