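# chipdecay=0.1.0 config_hash=7b42cb1c37d6 seed=2024
analysis	method	n	statistic	pvalue
occupancy_vs_residence	pearson	10	0.4822416999	0.1580857181
rp_vs_other_residence	mann-whitney-exact	2,8	11	0.5333333333
taf1_vs_residence	spearman	10	0.8666666667	0.00117353818
taf1_by_quartile	anova-tukey	3,2,2,3	8.95339708	0.01236862507
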