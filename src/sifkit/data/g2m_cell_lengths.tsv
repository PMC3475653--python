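strain_number	strain_name	protein	residue_change	mean_25C	stdev_25C	mean_30C	stdev_30C	n
275	M35	Cdk1	G43E	16.3	1.5	23.4	6.0	30
368	3w	Cdk1	C67Y	11.1	1.1	9.8	1.4	30
8	33	Cdk1	A177T	15.2	1.2	18.2	1.8	30
154	56/130	Cdk1	G183E	10.4	1.0	12.2	1.9	30
274	L7	Cdk1	P208S	16.4	1.0	17.6	2.0	30
515	M63	Cdk1	G227C	16.2	1.3	19.9	2.1	30
6	NA	CycB	C379Y	14.5	1.4	19.3	2.2	30
4932	NA	CycB	W395R	18.2	1.0	18.9	1.0	30
972	WT	NA	NA	12.8	1.6	14.5	1.1	30
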