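parameter,sex,age_lo,age_hi,mean,sd,source
BV/TV,M,61,70,19.2,5.00,normative_reference
Tb.Th,M,61,70,138,28,normative_reference
Tb.N,M,61,70,1.5,0.4,normative_reference
Ct.Wi,M,61,70,1.2,0.11,normative_reference
OV/BV,M,61,70,2.4,1.1,normative_reference
O.Th,M,61,70,8.6,2.5,normative_reference
OS/BS,M,61,70,12.4,4.2,normative_reference
Ob.S/BS,M,61,70,4.7,1.1,normative_reference
MS/BS,M,61,70,7.6,3.7,normative_reference
MAR,M,61,70,0.59,0.2,normative_reference
Aj.Ar,M,61,70,0.28,0.21,normative_reference
BFR/BS,M,61,70,16.4,9.7,normative_reference
BFR/BV,M,61,70,20.2,16.5,normative_reference
Mlt,M,61,70,17.8,7.3,normative_reference
ES/BS,M,61,70,3.5,1.5,normative_reference
Oc.S/BS,M,61,70,0.7,0.3,normative_reference
BV/TV,M,21,30,23.90,5.0,normative_reference
Tb.Th,M,21,30,141.00,27,normative_reference
Tb.N,M,21,30,1.70,0.4,normative_reference
Ct.Wi,M,21,30,1.28,0.43,normative_reference
OV/BV,M,21,30,3.60,1.90,normative_reference
O.Th,M,21,30,8.60,3.20,normative_reference
OS/BS,M,21,30,16.10,5.30,normative_reference
Ob.S/BS,M,21,30,5.40,2.00,normative_reference
MS/BS,M,21,30,7.80,1.90,normative_reference
MAR,M,21,30,0.64,0.12,normative_reference
Aj.Ar,M,21,30,0.41,0.12,normative_reference
BFR/BS,M,21,30,18.22,5.60,normative_reference
BFR/BV,M,21,30,25.40,8.90,normative_reference
Mlt,M,21,30,17.60,7.60,normative_reference
ES/BS,M,21,30,3.7,1.2,normative_reference
Oc.S/BS,M,21,30,0.6,0.3,normative_reference
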