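patient_id	response	age	sex	t_stage	n_stage	m_stage	grade
KC11	Progressive disease	62	Female	3	1	1	4
KC14	Progressive disease	68	Female	3	0	1	4
KC19	Partial response	46	Female	3	0	0	3
KC21	Progressive disease	41	Male	3	0	1	4
KC23	Progressive disease	53	Male	3	0	1	4
KC26	Stable disease	55	Male	3	0	1	4
KC36	Progressive disease	64	Female	3a	0	1	4
KC37	Partial response	54	Male	3a	0	1	4
KC46	Progressive disease	55	Male	3b	2	1	4
KC57	Progressive disease	58	Male	3b	0	1	4
KC92	Progressive disease	55	Male	3	0	0	3
KC93	Progressive disease	65	Female	2	0	0	2
KC96	Progressive disease	47	Male	3	0	0	3
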