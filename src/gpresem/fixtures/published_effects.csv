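source,target,b_direct,b_indirect,b_total,beta_direct,beta_indirect,beta_total
LMP,GPRE,0,-0.5628,-0.5628,0,-0.0419,-0.0419
Cu,GPRE,0.3795,-0.0012,0.3782,0.8252,-0.0026,0.8226
SAM,GPRE,-1.0138,0.6314,-0.3824,-0.2858,0.178,-0.1078
CHH_DNMV,GPRE,-3.0603,0.7791,-2.2811,-0.2530,0.0644,-0.1886
CHH_SV,GPRE,2.2539,0,2.2539,0.1578,0,0.1578
GSH,GPRE,1535.381,0,1535.381,0.3908,0,0.3908
LMP,GSH,0,0.0008,0.0008,0,0.2462,0.2462
Cu,GSH,0,0,0,0.3437,0,0.3437
SAM,GSH,0.0006,0,0.0006,0.6339,0,0.6339
LMP,CHH_SV,0,0.0552,0.0552,0,0.0586,0.0586
Cu,CHH_SV,-0.0166,0.0039,-0.0127,-0.5158,0.1203,-0.3955
SAM,CHH_SV,0,0.0375,0.0375,0,0.1509,0.1509
CHH_DNMV,CHH_SV,0.3457,0,0.3457,0.4082,0,0.4082
LMP,CHH_DNMV,0,0.1546,0.1546,0,0.1436,0.1436
Cu,CHH_DNMV,0.0112,0,0.0112,0.2947,0,0.2947
SAM,CHH_DNMV,0.1084,0,0.1084,0.3697,0,0.3697
LMP,SAM,1.4717,0,1.4717,0.3884,0,0.3884
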