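label,kind,source,target,estimate,se,critical_ratio,standardized,significance
lambda1,path,LMP,SAM,1.4717,0.582,2.5287,0.3884,*
lambda2,path,Cu,CHH_DNMV,0.0112,0.0056,2.0019,0.2947,*
lambda3,path,SAM,CHH_DNMV,0.1084,0.0432,2.5118,0.3697,*
lambda4,path,Cu,GSH,0.0,0.0,2.9726,0.3437,**
lambda5,path,CHH_DNMV,CHH_SV,0.3457,0.123,2.8115,0.4082,**
lambda6,path,SAM,GSH,0.0006,0.0001,5.4822,0.6339,***
lambda7,path,Cu,CHH_SV,-0.0166,0.0047,-3.5252,-0.5158,***
lambda8,path,Cu,GPRE,0.3795,0.0471,8.0586,0.8252,***
lambda9,path,GSH,GPRE,1535.381,438.3667,3.5025,0.3908,***
lambda10,path,SAM,GPRE,-1.0138,0.4032,-2.5143,-0.2858,*
lambda11,path,CHH_DNMV,GPRE,-3.0603,1.1604,-2.6373,-0.2530,**
lambda12,path,CHH_SV,GPRE,2.2539,1.2656,1.7809,0.1578,
"cov(Cu,LMP)",covariance,Cu,LMP,0.0038,0.0709,0.0536,,
delta1,residual_variance,SAM,SAM,0.1775,0.0418,4.2426,,***
delta2,residual_variance,CHH_DNMV,CHH_DNMV,0.0139,0.0033,4.2426,,***
delta3,residual_variance,GSH,GSH,0.0,0.0,4.2426,,***
delta4,residual_variance,CHH_SV,CHH_SV,0.0089,0.0021,4.2426,,***
delta5,residual_variance,GPRE,GPRE,0.5115,0.1206,4.2426,,***
var(Cu),variance,Cu,Cu,12.4414,2.9325,4.2426,,***
var(LMP),variance,LMP,LMP,0.0146,0.0034,4.2426,,***
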