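patient_id	response	age	sex	t_stage	n_stage	m_stage	grade
18	Partial response	66	Male	2	0	1	4
26	Stable disease	64	Female	3	2	1	4
27	Progressive disease	53	Male	3	0	1	4
31	Partial response	62	Male	2	2	0	3
36	Progressive disease	60	Male	2	0	0	2
37	Partial response	49	Female	3	1	1	4
46	Progressive disease	45	Male	3	0	0	3
49	Progressive disease	66	Female	3	0	0	3
54	Partial response	55	Female	2	0	0	2
58	Progressive disease	65	Female	3	1	0	3
60	Progressive disease	59	Male	2	0	0	2
62	Progressive disease	58	Male	1	0	0	1
72	Partial response	56	Female	3	1	0	3
73	Progressive disease	48	Male	3c	0	0	3
74	Partial response	53	Male	4	2	1	4
88	Stable disease	59	Female	3	0	0	3
91	Stable disease	67	Female	3	2	1	4
94	Progressive disease	74	Female	3	1	1	4
97	Partial response	70	Female	3	0	0	3
122	Partial response	61	Male	3a	0	0	3
128	Partial response	68	Female	3	0	1	4
135	Progressive disease	50	Male	3	0	0	3
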