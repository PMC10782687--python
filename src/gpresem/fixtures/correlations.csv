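variable,Cu,Ag,Time,CHH_DNMV,CHH_SV,LMP,SAM,GSH,GPRE
Cu,1,-0.181,-0.312,0.320,-0.386,0.009,0.075,0.385,0.807
Ag,-0.181,1,-0.203,-0.426,0.050,0.252,-0.020,-0.229,-0.201
Time,-0.312,-0.203,1,-0.028,0.607,-0.451,-0.116,0.081,-0.061
CHH_DNMV,0.320,-0.426,-0.028,1,0.247,0.039,0.389,0.171,0.005
CHH_SV,-0.386,0.050,0.607,0.247,1,-0.183,0.080,-0.132,-0.297
LMP,0.009,0.252,-0.451,0.039,-0.183,1,0.388,0.137,-0.117
SAM,0.075,-0.020,-0.116,0.389,0.080,0.388,1,0.650,-0.052
GSH,0.385,-0.229,0.081,0.171,-0.132,0.137,0.650,1,0.461
GPRE,0.807,-0.201,-0.061,0.005,-0.297,-0.117,-0.052,0.461,1
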