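sample_id	OTU_A	OTU_B	OTU_C	OTU_D	OTU_E
A_T2_PS_1	90	1000	5	98905	0
A_T2_PS_2	90	0	5	99905	0
A_T2_PS_3	0	0	5	99995	0
A_T6_PS_1	0	1000	5	98995	0
A_T6_PS_2	0	0	5	99995	0
A_T6_PS_3	0	0	5	99995	0
A_T7_PS_1	0	1000	5	98995	0
A_T7_PS_2	0	0	5	99995	0
A_T7_PS_3	0	0	5	99995	0
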