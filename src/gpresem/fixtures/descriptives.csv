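variable,minimum,maximum,mean,sd,variance,skewness,kurtosis
Cu,0.1,10.0,5.4270,3.5759,12.787,-0.102,-1.008
Ag,0.0,60.0,22.4324,26.7089,713.363,0.704,-1.480
Time,35.0,49.0,43.7027,5.8112,33.770,-0.495,-1.371
CHH_DNMV,0.3600,0.7600,0.5838,0.1370,0.019,-0.194,-1.054
CHH_SV,8.4800,8.9100,8.6546,0.1146,0.013,-0.079,-0.754
LMP,0.3583,0.9473,0.5512,0.1223,0.015,0.951,1.406
SAM,2.6528,4.6522,3.9617,0.4635,0.215,-0.709,0.278
GSH,0.0041,0.0060,0.0051,0.0004,0.000,-0.351,0.054
GPRE,0.7140,6.0610,2.5563,1.6589,2.752,0.932,-0.122
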