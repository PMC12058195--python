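# Synthetic stand-in ROI -> network assignment for a 122-ROI parcellation.
# Cortical block sizes are plausible but NOT an atlas table; the final
# 8 ROIs are subcortical (SUB). Replace with a real atlas table for real data.
roi_index	label
0	VIS
1	VIS
2	VIS
3	VIS
4	VIS
5	VIS
6	VIS
7	VIS
8	VIS
9	VIS
10	VIS
11	VIS
12	VIS
13	VIS
14	VIS
15	VIS
16	VIS
17	VIS
18	SOM
19	SOM
20	SOM
21	SOM
22	SOM
23	SOM
24	SOM
25	SOM
26	SOM
27	SOM
28	SOM
29	SOM
30	SOM
31	SOM
32	SOM
33	SOM
34	DAN
35	DAN
36	DAN
37	DAN
38	DAN
39	DAN
40	DAN
41	DAN
42	DAN
43	DAN
44	DAN
45	DAN
46	DAN
47	DAN
48	VAN
49	VAN
50	VAN
51	VAN
52	VAN
53	VAN
54	VAN
55	VAN
56	VAN
57	VAN
58	VAN
59	VAN
60	VAN
61	VAN
62	LIM
63	LIM
64	LIM
65	LIM
66	LIM
67	LIM
68	LIM
69	LIM
70	LIM
71	LIM
72	FPN
73	FPN
74	FPN
75	FPN
76	FPN
77	FPN
78	FPN
79	FPN
80	FPN
81	FPN
82	FPN
83	FPN
84	FPN
85	FPN
86	FPN
87	FPN
88	FPN
89	FPN
90	FPN
91	FPN
92	DMN
93	DMN
94	DMN
95	DMN
96	DMN
97	DMN
98	DMN
99	DMN
100	DMN
101	DMN
102	DMN
103	DMN
104	DMN
105	DMN
106	DMN
107	DMN
108	DMN
109	DMN
110	DMN
111	DMN
112	DMN
113	DMN
114	SUB
115	SUB
116	SUB
117	SUB
118	SUB
119	SUB
120	SUB
121	SUB
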