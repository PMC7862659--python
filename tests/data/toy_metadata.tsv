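sample_id	cultivar	soil	timepoint	replicate	storage_days
A_T2_PS_1	A	PS	T2	1	150
A_T2_PS_2	A	PS	T2	2	150
A_T2_PS_3	A	PS	T2	3	150
A_T6_PS_1	A	PS	T6	1	150
A_T6_PS_2	A	PS	T6	2	150
A_T6_PS_3	A	PS	T6	3	150
A_T7_PS_1	A	PS	T7	1	150
A_T7_PS_2	A	PS	T7	2	150
A_T7_PS_3	A	PS	T7	3	150
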