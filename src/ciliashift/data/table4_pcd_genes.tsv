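gene	alias	probe_id	multi_probe	log2_case	log2_control	regulation	log2_fc	fold_change	t_pvalue
ARMC4		4200274	0	8.327165	9.390315	down	1.06315	2.089488	0.130237
C19ORF52	DNAAF3	6290253	0	7.118648	6.746589	up	-0.372059	0.77267895	0.132469
C21ORF59		7040162	1	10.05058	10.54353	down	0.492947	1.407317	0.212658
C6ORF206	RSPH9	840433	0	8.570299	9.296023	down	0.72572	1.653725749	0.135019
CCDC103		6770463	0	7.065492	7.691135	down	0.62564	1.542895124	0.240855
CCDC114		7210482	0	6.548517	8.35885	down	1.81033	3.507225031	0.017073
CCDC40		4150072	1	2.886536	2.4908	up	-0.395737	0.76010098	0.150259
CCDC65		2370228	0	7.4877	8.417493	down	0.929793	1.905002	0.151083
DNAH11		7330360	1	3.002923	5.663427	down	2.6605	6.322521334	0.004405
DNAH5		2350554	0	2.840433	5.349519	down	2.50909	5.692608957	0.003368
DNAI1		2810300	0	8.674844	9.844953	down	1.17011	2.250288539	0.040018
DNAI2		5960685	0	7.177193	8.689865	down	1.51267	2.85337626	0.006119
DNAL1		6100682	1	3.770269	5.508203	down	1.73793	3.335562329	0.007245
DYX1C1		3140523	1	4.361447	5.485308	down	1.123861	2.179294	0.071072
HEATR2		5290037	1	8.210407	8.386503	down	0.1761	1.129825525	0.494105
HYDIN		7550360	1	6.950931	9.07216	down	2.12123	4.350647105	0.000905
KTU	DNAAF2	2490408	0	6.58843	6.791816	down	0.20339	1.151400704	0.579292
LRRC50	DNAAF1	5550035	0	8.577057	10.22783	down	1.65077	3.140011842	0.010513
LRRC6		2350477	0	6.796389	7.90332	down	1.10693	2.153868244	0.08437
ODF1		3120427	0	2.669272	3.925799	down	1.25653	2.38920393	0.046691
RPGR		2750386	1	2.726082	3.783812	down	1.05773	2.081653578	0.065558
RSHL3	RSPH4A	2630519	1	9.918507	10.80253	down	0.88402	1.845510569	0.187161
RSPH1		6020451	0	10.40699	11.50298	down	1.095986	2.137591	0.105587
ZMYND10		4540066	0	8.938617	10.15335	down	1.214728	2.320971	0.012449
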