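variable,Cu,Ag,Time,CHH_DNMV,CHH_SV,LMP,SAM,GSH,GPRE
Cu,,,,,*,,,*,**
Ag,,,,**,,,,,
Time,,,,,**,**,,,
CHH_DNMV,,**,,,,,*,,
CHH_SV,*,,**,,,,,,
LMP,,,**,,,,*,,
SAM,,,,*,,*,,**,
GSH,*,,,,,,**,,**
GPRE,**,,,,,,,**,
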