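ODA	ODA	DNAH11	DNAH5	DNAH9	DNAI1	DNAI2	DNAL1	TCTE1	TCTE3
IDA	IDA	DNAH1	DNAH10	DNAH12L	DNAH2	DNAH3	DNAH7	DNHD2	DNHL1	WDR63	WDR78
radial_spoke	radial_spoke	RSPH3	RSHL3	NME5	RSPH1	C6ORF206	RSPH10B	PPIL6	DNAJB13
IFT	IFT	DYNC2H1	DYNC2LI1	IFT122	IFT140	IFT172	IFT52	IFT57	IFT74	IFT80	IFT81	IFT88
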