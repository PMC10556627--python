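# chipdecay=0.1.0 config_hash=7b42cb1c37d6 seed=2024
group	bin	mean	ci_lo	ci_hi	n	ci_defined
long	0	4.338655409	2.686891733	5.990419085	3	True
long	1	4.309041637	2.747201404	5.87088187	3	True
long	2	4.326229153	2.964277038	5.688181267	3	True
long	3	4.374145539	2.7192679	6.029023179	3	True
long	4	4.293098165	3.084502884	5.501693446	3	True
long	5	4.31636221	2.71123416	5.92149026	3	True
long	6	4.350036691	3.044181674	5.655891708	3	True
long	7	4.355680063	2.855502683	5.855857443	3	True
long	8	4.320007692	2.733597787	5.906417597	3	True
long	9	4.357848145	2.862598654	5.853097637	3	True
long	10	4.287187377	2.902089502	5.672285253	3	True
long	11	4.336157664	3.150122852	5.522192475	3	True
long	12	4.343001167	3.05919297	5.626809364	3	True
long	13	4.373368458	2.812644347	5.934092569	3	True
long	14	4.395112195	3.082006116	5.708218274	3	True
long	15	4.337663369	2.973426104	5.701900635	3	True
long	16	4.337896398	2.927681877	5.74811092	3	True
long	17	4.31384357	2.987714443	5.639972696	3	True
long	18	4.40310645	2.928345059	5.877867841	3	True
long	19	4.343020237	2.84969845	5.836342024	3	True
longest	0	4.973882111	3.404969311	6.542794912	2	True
longest	1	4.957908978	3.143808167	6.772009789	2	True
longest	2	5.025434838	4.4635275	5.587342175	2	True
longest	3	5.078659724	5.057965554	5.099353894	2	True
longest	4	5.013569818	4.692563599	5.334576037	2	True
longest	5	4.886968599	4.576826353	5.197110844	2	True
longest	6	4.936320922	4.514060039	5.358581805	2	True
longest	7	4.849817103	3.690513275	6.009120931	2	True
longest	8	4.985087623	4.598830598	5.371344648	2	True
longest	9	4.986690884	4.158716848	5.81466492	2	True
longest	10	4.965946667	4.136472076	5.795421258	2	True
longest	11	4.999461637	3.952340381	6.046582892	2	True
longest	12	5.035236278	4.345781383	5.724691172	2	True
longest	13	5.070847815	3.954317698	6.187377933	2	True
longest	14	4.799875877	3.403650015	6.19610174	2	True
longest	15	4.959161759	3.464743938	6.453579579	2	True
longest	16	4.976130352	4.961378104	4.990882601	2	True
longest	17	5.066620603	4.265082548	5.868158658	2	True
longest	18	4.869708999	4.854615871	4.884802127	2	True
longest	19	4.949287158	4.646399578	5.252174739	2	True
short	0	3.525121075	-3.511752664	10.56199481	2	True
short	1	3.492924373	-3.309293928	10.29514267	2	True
short	2	3.535947198	-1.547147258	8.619041653	2	True
short	3	3.505082666	-2.203980099	9.21414543	2	True
short	4	3.540845541	-2.783569694	9.865260776	2	True
short	5	3.547516666	-2.741596933	9.836630265	2	True
short	6	3.510648309	-2.084614982	9.1059116	2	True
short	7	3.5014193	-3.322719759	10.32555836	2	True
short	8	3.58470758	-2.0878315	9.257246661	2	True
short	9	3.587657777	-2.217230485	9.392546039	2	True
short	10	3.446170045	-3.074689371	9.96702946	2	True
short	11	3.574689783	-2.571333726	9.720713292	2	True
short	12	3.507927413	-3.386329938	10.40218476	2	True
short	13	3.497754503	-2.684943291	9.680452297	2	True
short	14	3.51849565	-3.559307916	10.59629922	2	True
short	15	3.501120971	-3.347365716	10.34960766	2	True
short	16	3.471770224	-2.913126737	9.856667186	2	True
short	17	3.501876151	-2.72302637	9.726778672	2	True
short	18	3.407203057	-2.849285517	9.663691631	2	True
short	19	3.52702926	-2.238134423	9.292192944	2	True
shortest	0	2.658722311	1.27575827	4.041686352	3	True
shortest	1	2.638375512	1.311583074	3.96516795	3	True
shortest	2	2.687290296	1.18941341	4.185167183	3	True
shortest	3	2.671299047	1.166023524	4.176574571	3	True
shortest	4	2.649622824	1.238542767	4.060702882	3	True
shortest	5	2.641958932	1.272385779	4.011532084	3	True
shortest	6	2.669075513	1.308884943	4.029266083	3	True
shortest	7	2.674100765	1.196638952	4.151562579	3	True
shortest	8	2.636755732	1.262252063	4.0112594	3	True
shortest	9	2.663090066	1.247433775	4.078746357	3	True
shortest	10	2.669880551	1.246897342	4.09286376	3	True
shortest	11	2.669344793	1.236019083	4.102670503	3	True
shortest	12	2.677588012	1.283777458	4.071398565	3	True
shortest	13	2.655129614	1.265706648	4.04455258	3	True
shortest	14	2.691235607	1.14279074	4.239680475	3	True
shortest	15	2.72486734	1.254906268	4.194828412	3	True
shortest	16	2.653192432	1.264986825	4.04139804	3	True
shortest	17	2.687973609	1.231488208	4.14445901	3	True
shortest	18	2.683069954	1.204759103	4.161380804	3	True
shortest	19	2.630960435	1.294634087	3.967286783	3	True
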