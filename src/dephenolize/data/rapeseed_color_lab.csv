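parameter,Pdp,Pe,Pus,Pdp-us,Popt
L_star,50.34,49.80,51.88,47.78,31.46
a_star,6.02,5.08,5.21,5.83,3.43
b_star,18.10,17.20,20.52,17.86,7.45
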