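gene_id	qvalue_AvsB	log2fc_BvsA	pvalue_AvsB	ec_number
TRINITY_DN26985_c0_g1_i1-A1	0.002654807	1.513842229	0.0000299	EC:4.1.2.13
TRINITY_DN64_c0_g1_i1-A1	0.026921138	0.738460022	0.0007902	EC:4.1.2.13
TRINITY_DN64_c0_g1_i2-A1	0.005398428	1.417834419	0.0000761	EC:4.1.2.13
TRINITY_DN1200_c0_g1_i1-A1	0.038090126	0.992662495	0.0013437	EC:5.3.1.6
TRINITY_DN5382_c0_g1_i1-A1	0.029219008	0.728632982	0.0008935	EC:5.3.1.6
TRINITY_DN163_c0_g1_i2-A1	0.033252883	-0.716435144	0.0010878	EC:4.1.1.39
TRINITY_DN7631_c0_g3_i2-A1	0.005903226	1.076873143	0.0000853	EC:3.1.3.11
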