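gene_id	log2fc_BvsA	qvalue_AvsB	log2fc_CvsD	qvalue_DvsC	log2fc_CvsA	qvalue_AvsC
TRINITY_DN1877_c1_g1_i1-A1	0.86039	0.01941	1.19700	0.00000	1.29359	0.00000
TRINITY_DN2953_c0_g2_i1-A1	-0.60210	0.03757	-0.73871	0.00001	-0.64054	0.00066
TRINITY_DN19661_c0_g1_i1-A1			-1.75354	0.00001
TRINITY_DN2735_c0_g1_i1-A1			-0.72304	0.02554
TRINITY_DN8140_c0_g2_i1-A1			-1.04692	0.00724
TRINITY_DN8663_c0_g1_i1-A1			-0.87317	0.00001
TRINITY_DN1054_c1_g2_i2-A1					-0.56104	0.00050
TRINITY_DN19661_c0_g1_i1-A1					-1.13608	0.00476
TRINITY_DN2735_c0_g1_i1-A1					-0.87518	0.00190
TRINITY_DN8140_c0_g2_i1-A1					-0.79315	0.04115
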