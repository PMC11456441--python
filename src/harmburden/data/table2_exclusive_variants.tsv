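index	chrom	gene	location	ref	alt	predict_domain	n_han_asd	n_spark_asd
1	chr15	IGF1R	99434814	G	A	Furin-like	1	.
2	chr15	IGF1R	98707687	C	T	LCR	.	2
3	chr15	IGF1R	98708078	G	A	FU	.	1
4	chr15	IGF1R	98891579	C	T	FU	.	1
5	chr15	IGF1R	98911351	C	T	FN3	.	1
6	chr15	IGF1R	98913054	A	C	FN3	.	1
7	chr15	IGF1R	98934854	G	A	.	.	1
8	chr15	IGF1R	98939339	G	T	TyrKc	.	1
9	chr15	IGF1R	98948659	G	A	TyrKc	.	1
10	chr15	IGF1R	98957383	A	G	.	.	1
11	chr2	IGFBP5	217541592	C	T	Thyroglobulin_1	1	.
12	chr14	AKT1	105239823	G	A	STKc_PKB_alpha	1	.
13	chr14	AKT1	105241519	T	C	STKc_PKB_alpha	1	.
14	chr15	MAP2K1	66727430	G	A	.	1	.
15	chr17	RPS6KB1	57990136	C	T	S_TKc	2	.
16	chr19	MAP2K2	4102403	C	T	PKc_MEK2	1	.
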