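population,density_2019,density_lo,density_hi
CG,0.300,0,3.0
JC,0.725,0,2.0
DC,23.825,0,138.4
VP,9.325,0,32.1
LG,6.575,0,23.1
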