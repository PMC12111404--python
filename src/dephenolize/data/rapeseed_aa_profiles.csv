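amino_acid,class,Pdp,Pe,Pus,Pdp-us,Popt
Thr,EAA,4.55,5.20,4.94,4.56,4.97
Val,EAA,5.14,5.27,5.14,5.42,5.93
Met,EAA,3.10,2.58,2.58,3.02,3.35
Ile,EAA,4.31,4.58,4.35,4.21,4.44
Leu,EAA,6.71,7.10,6.73,6.83,7.57
Phe,EAA,4.83,5.14,4.96,4.65,4.96
Lys,EAA,6.95,6.21,6.65,6.71,7.24
His,EAA,2.97,2.71,2.76,2.57,2.86
Asp,NEAA,8.42,9.21,8.92,9.07,9.47
Ser,NEAA,4.94,5.23,5.20,5.12,5.55
Glu,NEAA,13.68,13.11,13.19,15.20,16.79
Gly,NEAA,4.21,4.16,4.10,4.61,5.14
Ala,NEAA,4.04,4.07,4.05,4.35,5.01
Tyr,NEAA,3.30,3.95,3.70,3.18,3.16
Arg,NEAA,8.30,7.55,8.14,7.90,6.32
Pro,NEAA,6.16,5.05,5.38,5.61,5.82
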