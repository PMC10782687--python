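index,value
chi_square,8.4558
p_value,0.3903
chi_square_over_df,1.057
rmr,0.0264
gfi,0.944
agfi,0.8039
pgfi,0.2697
nfi,0.9319
rfi,0.8213
ifi,0.9961
tli,0.9884
cfi,0.9956
pnfi,0.381
pcfi,0.355
rmsea,0.0379
rmsea_lo90,0.0
rmsea_hi90,0.2021
pclose,0.4581
srmr,0.0719
ecvi,1.346
ecvi_lo90,1.33
ecvi_hi90,1.66
hoelter_05,67
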