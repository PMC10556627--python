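# chipdecay=0.1.0 config_hash=7b42cb1c37d6 seed=2024
peak_id	chrom	summit	gene_id	distance	is_rp	is_subtelomeric	quartile
peak_00001	chr_syn1	18966	RPL10	202	True	False	long
peak_00002	chr_syn1	32704	GENE0001	115	False	False	longest
peak_00003	chr_syn1	42369	GENE0002	278	False	False	long
peak_00004	chr_syn1	54857	GENE0003	99	False	False	short
peak_00005	chr_syn2	19270	GENE0004	200	False	False	shortest
peak_00006	chr_syn2	31238	GENE0005	93	False	False	unassigned
peak_00007	chr_syn2	45635	GENE0006	173	False	False	longest
peak_00008	chr_syn2	57198	RPL11A	173	True	False	long
peak_00009	chr_syn3	21662	GENE0008	260	False	False	short
peak_00010	chr_syn3	33984	GENE0009	113	False	False	unassigned
peak_00011	chr_syn3	42314	GENE0010	57	False	False	shortest
peak_00012	chr_syn3	54569	GENE0011	136	False	False	shortest
peak_control_flat	chr_syn4	21472	.	-1	False	False	unassigned
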