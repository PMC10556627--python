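# chipdecay=0.1.0 config_hash=7b42cb1c37d6 seed=2024
analysis	group1	group2	mean_diff	p_adj
taf1_by_quartile	long	longest	0.7779683266	0.4614096528
taf1_by_quartile	long	short	-0.7912897978	0.4488051118
taf1_by_quartile	long	shortest	-1.625460716	0.0402587078
taf1_by_quartile	longest	short	-1.569258124	0.09956391105
taf1_by_quartile	longest	shortest	-2.403429043	0.01152399497
taf1_by_quartile	short	shortest	-0.8341709186	0.4097394465
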