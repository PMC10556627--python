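# chipdecay=0.1.0 config_hash=7b42cb1c37d6 seed=2024
quartile	n	median_residence_min	mean_residence_min
shortest	3	4.892176786	4.34951848
short	2	5.561905675	5.561905675
long	3	8.665986033	9.90439978
longest	2	16.66021769	16.66021769
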