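protein_a	a_start	a_end	protein_b	b_start
P13611-3	1	347	P13611-2	1
P13611-3	1336	1680	P13611-2	2103
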