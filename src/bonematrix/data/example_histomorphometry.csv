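case,sex,age,parameter,value
case1,M,61,BV/TV,22.19
case1,M,61,Tb.Th,134.71
case1,M,61,Tb.N,1.65
case1,M,61,Ct.Wi,0.78
case1,M,61,Ct.Po,4.46
case1,M,61,OV/BV,2.73
case1,M,61,O.Th,4.1
case1,M,61,OS/BS,50.33
case1,M,61,Ob.S/BS,7.45
case1,M,61,MS/BS,3.8
case1,M,61,MAR,0.7
case1,M,61,Aj.Ar,0.053
case1,M,61,BFR/BS,9.73
case1,M,61,BFR/BV,14.91
case1,M,61,Mlt,77.38
case1,M,61,ES/BS,8.67
case1,M,61,Oc.S/BS,0.28
case1,M,61,N.Oc/BS,0.1
case2,M,29,BV/TV,22.55
case2,M,29,Tb.Th,91.83
case2,M,29,Tb.N,2.46
case2,M,29,Ct.Wi,0.41
case2,M,29,Ct.Po,38.60
case2,M,29,OV/BV,1.51
case2,M,29,O.Th,4.22
case2,M,29,OS/BS,21.31
case2,M,29,Ob.S/BS,0.46
case2,M,29,MS/BS,2.62
case2,M,29,MAR,0.70
case2,M,29,Aj.Ar,0.09
case2,M,29,BFR/BS,6.73
case2,M,29,BFR/BV,14.66
case2,M,29,Mlt,48.78
case2,M,29,ES/BS,16.25
case2,M,29,Oc.S/BS,1.9
case2,M,29,N.Oc/BS,0.48
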