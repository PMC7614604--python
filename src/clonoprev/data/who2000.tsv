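age_group	std_weight
0-4	8860
5-9	8690
10-14	8600
15-19	8470
20-24	8220
25-29	7930
30-34	7610
35-39	7150
40-44	6590
45-49	6040
50-54	5370
55-59	4550
60-64	3720
65-69	2960
70-74	2210
75-79	1520
80-84	910
85+	630
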