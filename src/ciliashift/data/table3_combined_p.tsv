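category	k	p_combined
IDA	10	3.188885e-12
ODA	8	3.524812e-08
radial_spoke	8	0.0001061203
IFT	11	1.275819e-07
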