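# chipdecay=0.1.0 config_hash=7b42cb1c37d6 seed=2024
peak_id	chrom	summit	y0	yf	lrc	koff_per_min	residence_min	se_lrc	p_lrc	rss	df	converged	retained
peak_00001	chr_syn1	18966	61.21490673	22.1553675	-2.56789592	0.07669675185	13.03836181	0.6493773835	0.00225562227	1479.256988	11	True	True
peak_00002	chr_syn1	32704	285.7014902	69.5500204	-2.802569004	0.06065404183	16.48694744	0.6030773184	0.0007083991176	31964.88918	11	True	True
peak_00003	chr_syn1	42369	45.64292478	7.609855089	-2.159405712	0.1153936778	8.665986033	0.598123257	0.004095382318	1476.130203	11	True	True
peak_00004	chr_syn1	54857	103.5781143	23.44882406	-1.724164014	0.1783220642	5.607831002	0.5231633773	0.007132823323	5757.105053	11	True	True
peak_00005	chr_syn2	19270	99.52676638	25.09547333	-1.059120033	0.3467608141	2.883832196	0.456013389	0.04039498127	3983.935203	11	True	True
peak_00006	chr_syn2	31238	65.03164829	1.709749242	-0.7621552597	0.4666595698	2.142889731	0.4251871718	0.1005630376	2305.929235	11	True	False
peak_00007	chr_syn2	45635	135.0702812	16.10371666	-2.823370232	0.05940539502	16.83348793	0.75158371	0.0031735535	14714.8684	11	True	True
peak_00008	chr_syn2	57198	99.38658996	14.03731352	-2.080547368	0.1248618482	8.008851501	0.5436635043	0.002809404537	6331.127975	11	True	True
peak_00009	chr_syn3	21662	195.4780669	49.14502196	-1.707649397	0.1812914363	5.515980348	0.5011517907	0.005851555372	17687.81477	11	True	True
peak_00010	chr_syn3	33984	59.95438547	6.821722766	-0.8155490613	0.4423963579	2.260416439	0.372423725	0.05098230475	1273.198316	11	True	False
peak_00011	chr_syn3	42314	98.45921597	13.28594473	-1.662513445	0.1896616764	5.272546457	0.2298632862	1.680984401e-05	1273.614929	11	True	True
peak_00012	chr_syn3	54569	49.56330614	15.48393546	-1.587637355	0.2044079852	4.892176786	0.2317431314	2.761074044e-05	210.4423944	11	True	True
peak_control_flat	chr_syn4	21472	83.21250371	70.79178907	15.11279106	3659331.584	2.73273951e-07	inf		6469.325183	11	False	False
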