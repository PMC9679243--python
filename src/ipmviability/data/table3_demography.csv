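population,lambda_s_median,lambda_s_lo,lambda_s_hi,pr_ext_mean,pr_ext_lo,pr_ext_hi,pred_n2019_mean,pred_n2019_lo,pred_n2019_hi
CG,0.539,0.337,0.799,0.901,0,1,48.3,0,9
JC,0.319,0.175,0.517,1.000,1,1,0,0,0
DC,0.494,0.358,0.709,0.959,0.099,1,31.4,0,1
VP,0.602,0.412,0.785,0.960,0.168,1,0.05,0,1
LG,0.407,0.225,0.626,0.999,1,1,0,0,0
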