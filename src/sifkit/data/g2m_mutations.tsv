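protein	residue_change	impact_class	ddg_monomer	ddg_complex	ensemble	c_kd_cycb	c_kd_cdk1	c_j_combined	sif_published
Cdk1	G43E	S	2.10	24.9	-	-	0.011	-	0.27
Cdk1	C67Y	S	3.17	1.31	-	-	0.011	-	0.035
Cdk1	A177T	F	5.97	3.65	-	-	-	0.011	0.066
Cdk1	G183E	F	3.72	4.13	-	-	-	0.011	0.045
Cdk1	P208S	F	3.56	2.35	-	-	-	0.011	0.039
Cdk1	G227C	S	7.69	7.23	-	-	0.011	-	0.085
CycB	C379Y	S	31.92	34.56	-	0.004	-	-	0.138
CycB	W395R	S	6.57	6.15	-	0.004	-	-	0.026
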