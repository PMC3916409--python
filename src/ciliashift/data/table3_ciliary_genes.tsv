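gene	alias	category	multi_probe	log2_case	log2_control	regulation	log2_fc	fold_change	p_wilcoxon
DNAH1		IDA	0	7.099971713	8.823093021	Down	1.72312131	3.301499231	0.002397602
DNAH10		IDA	1	2.845467386	2.930532774	Down	0.08506539	1.060735818	0.297612503
DNAH12L		IDA	0	2.984792693	4.691691968	Down	1.70689927	3.264584241	0.005496876
DNAH2		IDA	0	8.605120088	10.73227718	Down	2.12715709	4.368557834	0.001398601
DNAH3		IDA	0	5.76933297	8.094913833	Down	2.32558086	5.012675559	0.005605302
DNAH7		IDA	0	6.514024915	8.269907386	Down	1.75588247	3.377328402	0.003796204
DNHD2		IDA	0	8.860690672	10.45193877	Down	1.59124809	3.01309903	0.017982018
DNHL1		IDA	1	2.704540406	3.102569317	Down	0.39802891	1.317706357	0.069468652
WDR63		IDA	0	6.410269672	8.011632917	Down	1.60136324	3.034298967	0.017982018
WDR78		IDA	1	4.278425094	5.226285631	Down	0.94786054	1.92900989	0.024775225
DNAH11		ODA	0	3.002922837	5.663426945	Down	2.66050411	6.322539346	0.002598476
DNAH5		ODA	0	2.840433314	5.349519237	Down	2.50908592	5.692592858	0.010311612
DNAH9		ODA	1	4.195042679	4.979603695	Down	0.78456102	1.722568101	0.008791209
DNAI1		ODA	0	8.674843985	9.844952993	Down	1.17010901	2.250286995	0.033166833
DNAI2		ODA	0	7.177192762	8.6898654	Down	1.51267264	2.853381481	0.002397602
DNAL1		ODA	1	5.239162724	5.900496355	Down	0.66133363	1.58154393	0.163836164
TCTE1		ODA	0	3.213232157	4.82357751	Down	1.61034535	3.053249212	0.007662144
TCTE3		ODA	0	2.361725905	2.586822518	Down	0.22509661	1.168855518	0.617456403
RSPH3		radial_spoke	0	7.413315798	7.836831773	Down	0.42351598	1.341192183	0.227972028
RSHL3	RSPH4A	radial_spoke	1	9.513876417	10.3676621	Down	0.85378569	1.807236971	0.136063936
NME5	RSPH23	radial_spoke	0	9.938877607	10.88896095	Down	0.95008335	1.931984273	0.264335664
RSPH1		radial_spoke	0	10.4069913	11.50297723	Down	1.09598593	2.137591135	0.072327672
C6ORF206	RSPH9	radial_spoke	0	8.57029857	9.296022759	Down	0.72572419	1.653730552	0.163836164
RSPH10B		radial_spoke	1	4.839311246	5.755622796	Down	0.91631155	1.887284017	0.005994006
PPIL6	RSPH12	radial_spoke	0	6.766706564	8.011535825	Down	1.24482926	2.369905052	0.111888112
DNAJB13		radial_spoke	0	4.103136217	5.749770835	Down	1.64663462	3.131024115	0.033166833
DYNC2H1		IFT	0	6.048332879	8.057745569	Down	2.00941269	4.026182839	0.002397602
DYNC2LI1		IFT	1	5.614105936	5.886374416	Down	0.27226848	1.20770532	0.264335664
IFT122		IFT	1	4.919297327	5.396632088	Down	0.47733476	1.39216939	0.008791209
IFT140		IFT	0	6.501863507	7.674088316	Down	1.17222481	2.253589598	0.017982018
IFT172		IFT	0	8.232366019	9.177805846	Down	0.94543983	1.925775902	0.017982018
IFT52		IFT	1	6.3875103	6.531748043	Down	0.14423774	1.105146586	0.303496503
IFT57		IFT	0	8.12299147	9.303622084	Down	1.18063061	2.266758367	0.033166833
IFT74		IFT	0	7.712753509	8.095831669	Down	0.38307816	1.304121386	0.227972028
IFT80		IFT	1	2.430337143	2.764181897	Down	0.33384475	1.260367755	0.100406593
IFT81		IFT	1	3.80548032	4.32006191	Down	0.51458159	1.428579763	0.194205794
IFT88		IFT	1	4.97817553	5.909540297	Down	0.93136477	1.907079214	0.033166833
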