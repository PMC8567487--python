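parameter,mean,sd,source
CaMean,22.2,0.45,adult_trabecular_reference
CaPeak,22.94,0.39,adult_trabecular_reference
CaWidth,3.35,0.34,adult_trabecular_reference
CaLow,4.93,1.57,adult_trabecular_reference
CaHigh,5.55,3.32,adult_trabecular_reference
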