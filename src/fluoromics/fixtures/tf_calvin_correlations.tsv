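tf_id	gene_id	pcc	pvalue
TRINITY_DN1877_c1_g1_i1-A1	TRINITY_DN1200_c0_g1_i1-A1	0.933296371	0.006525666
TRINITY_DN1877_c1_g1_i1-A1	TRINITY_DN163_c0_g1_i2-A1	-0.963016176	0.002026412
TRINITY_DN1877_c1_g1_i1-A1	TRINITY_DN26985_c0_g1_i1-A1	0.976969538	0.000789496
TRINITY_DN1877_c1_g1_i1-A1	TRINITY_DN64_c0_g1_i1-A1	0.988595464	0.000194354
TRINITY_DN1877_c1_g1_i1-A1	TRINITY_DN64_c0_g1_i2-A1	0.964488272	0.001869233
TRINITY_DN2953_c0_g2_i1-A1	TRINITY_DN1200_c0_g1_i1-A1	-0.951440039	0.003479851
TRINITY_DN2953_c0_g2_i1-A1	TRINITY_DN163_c0_g1_i2-A1	0.958290919	0.002573192
TRINITY_DN2953_c0_g2_i1-A1	TRINITY_DN26985_c0_g1_i1-A1	-0.982354731	0.000464286
TRINITY_DN2953_c0_g2_i1-A1	TRINITY_DN64_c0_g1_i1-A1	-0.968181729	0.001502497
TRINITY_DN2953_c0_g2_i1-A1	TRINITY_DN64_c0_g1_i2-A1	-0.971121463	0.001238913
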