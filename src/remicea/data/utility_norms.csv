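age_lo,age_hi,sex,utility
16,44,F,0.93
16,44,M,0.93
45,54,F,0.83
45,54,M,0.87
55,64,F,0.79
55,64,M,0.8
65,74,F,0.78
65,74,M,0.78
75,120,F,0.71
75,120,M,0.75
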