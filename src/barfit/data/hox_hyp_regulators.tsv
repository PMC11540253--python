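regulator	promoter
hoxA	P_MBH
hoxA	P_SH
hypA1	P_reg
hypB1	P_reg
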