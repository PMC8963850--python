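patient_id	response	age	sex	t_stage	n_stage	m_stage	grade
III-1	Partial response	67	Male	3	0	1	4
III-2	Stable disease	45	Female	2	0	0	2
III-3	Partial response	48	Female	3	0	0	3
III-4	Progressive disease	65	Female	1	0	1	4
III-5	Progressive disease	59	Male	3	1	1	4
III-6	Progressive disease	53	Female	4	0	0	3
III-7	Progressive disease	58	Male	1	0	0	1
III-8	Progressive disease	51	Male	3b	2	1	4
III-9	Partial response	71	Female	4	1	0	3
III-10	Stable disease	59	Male	1	0	0	1
III-11	Stable disease	70	Male	3	1	1	4
III-12	Partial response	47	Male	3	1	1	4
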