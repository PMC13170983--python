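age,sex,q_diabetes,q_nondiabetes
54,F,0.003964,0.002239
55,F,0.004478,0.00253
56,F,0.005059,0.002858
57,F,0.005715,0.003229
58,F,0.006457,0.003647
59,F,0.007295,0.004121
60,F,0.008241,0.004655
61,F,0.009311,0.005259
62,F,0.010519,0.005942
63,F,0.011884,0.006713
64,F,0.013426,0.007584
65,F,0.015168,0.008568
66,F,0.017136,0.00968
67,F,0.019359,0.010936
68,F,0.021871,0.012355
69,F,0.024709,0.013958
70,F,0.027915,0.015769
71,F,0.031538,0.017815
72,F,0.03563,0.020126
73,F,0.040253,0.022738
74,F,0.045476,0.025688
75,F,0.051376,0.029021
76,F,0.058043,0.032787
77,F,0.065574,0.037041
78,F,0.074082,0.041847
79,F,0.083695,0.047277
80,F,0.094555,0.053412
81,F,0.106824,0.060342
82,F,0.120684,0.068172
83,F,0.136344,0.077017
84,F,0.154035,0.087011
85,F,0.174021,0.098301
86,F,0.196601,0.111055
87,F,0.222111,0.125465
88,F,0.250931,0.141745
89,F,0.28349,0.160137
90,F,0.320274,0.180915
91,F,0.361831,0.20439
92,F,0.408781,0.23091
93,F,0.461821,0.260872
94,F,0.521745,0.294721
95,F,0.589443,0.332962
96,F,0.665926,0.376166
97,F,0.752332,0.424975
98,F,0.849951,0.480117
99,F,0.85,0.542414
100,F,0.85,0.612794
101,F,0.85,0.692307
102,F,0.85,0.7
103,F,0.85,0.7
104,F,0.85,0.7
105,F,0.85,0.7
106,F,0.85,0.7
107,F,0.85,0.7
108,F,0.85,0.7
109,F,0.85,0.7
110,F,0.85,0.7
54,M,0.006342,0.003582
55,M,0.007165,0.004047
56,M,0.008094,0.004572
57,M,0.009145,0.005166
58,M,0.010331,0.005836
59,M,0.011672,0.006593
60,M,0.013186,0.007449
61,M,0.014897,0.008415
62,M,0.01683,0.009507
63,M,0.019014,0.010741
64,M,0.021481,0.012134
65,M,0.024269,0.013709
66,M,0.027418,0.015487
67,M,0.030975,0.017497
68,M,0.034994,0.019767
69,M,0.039535,0.022332
70,M,0.044665,0.02523
71,M,0.05046,0.028504
72,M,0.057007,0.032202
73,M,0.064404,0.036381
74,M,0.072761,0.041101
75,M,0.082202,0.046434
76,M,0.092868,0.052459
77,M,0.104918,0.059266
78,M,0.118532,0.066956
79,M,0.133912,0.075644
80,M,0.151287,0.085459
81,M,0.170918,0.096547
82,M,0.193095,0.109075
83,M,0.21815,0.123228
84,M,0.246456,0.139217
85,M,0.278434,0.157281
86,M,0.314562,0.177689
87,M,0.355378,0.200745
88,M,0.40149,0.226792
89,M,0.453585,0.256219
90,M,0.512439,0.289465
91,M,0.57893,0.327024
92,M,0.654049,0.369456
93,M,0.738914,0.417395
94,M,0.834791,0.471554
95,M,0.85,0.53274
96,M,0.85,0.601865
97,M,0.85,0.679959
98,M,0.85,0.7
99,M,0.85,0.7
100,M,0.85,0.7
101,M,0.85,0.7
102,M,0.85,0.7
103,M,0.85,0.7
104,M,0.85,0.7
105,M,0.85,0.7
106,M,0.85,0.7
107,M,0.85,0.7
108,M,0.85,0.7
109,M,0.85,0.7
110,M,0.85,0.7
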