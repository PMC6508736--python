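sample_id	group	histology	age	weight_lbs	height	fsh_miu_ml	eggs_injected	embryos
C1	CS	Normal spermatogenesis in 100% of tubules	32	176	5'7"	5.4	13	7
C2	CS	Normal spermatogenesis in 95% of tubules	55	278	5'7"	8.9	4	1
C3	CS	Mild hypospermatogenesis; focal germ cell degeneration	33	259	6'6"	10.03	14	6
C4	CS	Moderate hypospermatogenesis 50%; maturation arrest 15%; SCO 35%	31	181	5'9"		14	8
SCO5	SCO	SCO 100%	30	185	6'0"	15	13	9
SCO7	SCO	SCO 100%	24	174	5'5"	31.87	13	5
SCO8	SCO	SCO 100%	34	155	5'6"	15.2	20	16
SCO9	SCO	SCO 100%	42	304	6'0"	8.1	19	1
SCO10	SCO	SCO 100%	35	248	6'2"	22.42	8	1
SCO11	SCO	SCO 80%; severe hypospermatogenesis 20%	25	240	6'1"	15.39	11	3
SCO12	SCO	SCO 100%	36	136	5'7"	29	8	6
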