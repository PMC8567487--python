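case,compartment,parameter,value
case1,cortical,CaMean,22.39
case1,cortical,CaPeak,23.40
case1,cortical,CaWidth,4.33
case1,cortical,CaLow,6.42
case1,cortical,CaHigh,12.68
case1,trabecular,CaMean,20.86
case1,trabecular,CaPeak,22.0
case1,trabecular,CaWidth,5.89
case1,trabecular,CaLow,11.93
case1,trabecular,CaHigh,4.71
case2,cortical,CaMean,21.27
case2,cortical,CaPeak,22.01
case2,cortical,CaWidth,4.51
case2,cortical,CaLow,8.17
case2,cortical,CaHigh,4.48
case2,trabecular,CaMean,20.63
case2,trabecular,CaPeak,21.49
case2,trabecular,CaWidth,4.85
case2,trabecular,CaLow,10.54
case2,trabecular,CaHigh,2.22
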