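population,group,P,n_a,n_e,H_O,H_S,R_S,F_IS
CG,West,92.3,3.31,2.4,0.102,0.54,3.21,0.81
JC,East,7.7,1.08,1.05,0.006,0.03,1.08,0.81
DC,East,46.2,1.92,1.40,0.043,0.20,1.83,0.78
VP,East,30.8,1.31,1.13,0.030,0.09,1.30,0.66
LG,East,15.4,1.15,1.11,0.008,0.07,1.15,0.89
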