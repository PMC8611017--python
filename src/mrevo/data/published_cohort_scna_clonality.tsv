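patient	risk_group	n_clonal_segments	pct_genome_clonal	n_subclonal_segments	pct_genome_subclonal	n_samples	mycn_amplified
CB1001	HR	100	12	3	0.4	5	yes
CB1002	HR	644	79	105	13	5	no
CB1003	HR	54	7	57	7	10	yes
CB1004	HR	104	13	100	12	3	no
CB1005	HR	132	16	98	12	5	no
CB1007	LR	487	60	17	2	2	no
CB1008	HR	24	3	353	44	6	yes
CB1009	IMR	561	69	1	0.0	9	no
CB1010	HR	247	30	33	4	3	no
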