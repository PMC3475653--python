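protein	impact_class	channels	weights
H-Ras	F	ras_activation	1.0
H-Ras	S	ras_inactivation	1.0
Raf-1	F	raf_activation	1.0
Raf-1	S	raf_inactivation	1.0
B-Raf	F	raf_activation	1.0
B-Raf	S	raf_inactivation	1.0
Mek	F	mek_activation	1.0
Mek	S	mek_inactivation	1.0
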