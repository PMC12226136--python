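protein_id	domain_name	start	end
Q9P2N4-3	Pro	1	287
Q9P2N4-3	Mp	288	575
Q9P2N4-3	Dis	576	650
Q9P2N4-3	TSR	651	705
Q9P2N4-3	CR	706	780
Q9P2N4-3	Sp	781	877
P13611-2	G1	1	347
P13611-2	GAGbeta	348	2103
P13611-2	G3	2104	2409
P13611-3	G1	1	347
P13611-3	GAGalpha	348	1335
P13611-3	G3	1336	1680
P21810	Pro	1	80
P21810	LRR2/LRR3	126	126
P21810	LRR1	81	103
P21810	LRR2	104	125
P21810	LRR3	127	147
P21810	LRR4	148	178
P21810	LRR5	179	195
P21810	LRR6	196	218
P21810	LRR7	219	243
P21810	LRR8	244	264
P21810	LRR9	265	290
P21810	LRR10	291	315
P21810	LRR11	316	340
P21810	LRR12	341	368
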