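bone,volume_mean_mm3,volume_std_mm3,volume_cv,sa_mean_mm2,sa_std_mm2,sa_cv
pelvis,393000,53200,13.54,71100,6210,8.74
femur,645000,111000,17.23,72000,8770,12.17
patella,24100,4180,17.38,4760,564,11.85
tibia_fibula,358000,62100,17.33,67100,8990,13.40
foot,245000,34900,14.24,60300,6580,10.92
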