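age,sex,q
40,M,0.001453
41,M,0.001584
42,M,0.001728
43,M,0.001884
44,M,0.002055
45,M,0.002241
46,M,0.002443
47,M,0.002664
48,M,0.002906
49,M,0.003169
50,M,0.003455
51,M,0.003768
52,M,0.004109
53,M,0.004481
54,M,0.004887
55,M,0.005329
56,M,0.005811
57,M,0.006337
58,M,0.006911
59,M,0.007536
60,M,0.008218
61,M,0.008962
62,M,0.009773
63,M,0.010658
64,M,0.011622
65,M,0.012674
66,M,0.013821
67,M,0.015072
68,M,0.016437
69,M,0.017924
70,M,0.019546
71,M,0.021316
72,M,0.023245
73,M,0.025349
74,M,0.027643
75,M,0.030145
76,M,0.032873
77,M,0.035848
78,M,0.039093
79,M,0.042631
80,M,0.04649
81,M,0.050697
82,M,0.055286
83,M,0.06029
84,M,0.065746
85,M,0.071697
86,M,0.078186
87,M,0.085262
88,M,0.092979
89,M,0.101395
90,M,0.110572
91,M,0.120579
92,M,0.131492
93,M,0.143394
94,M,0.156372
95,M,0.170525
96,M,0.185958
97,M,0.202789
98,M,0.221143
99,M,0.241158
100,M,0.262985
101,M,0.286787
102,M,0.312744
103,M,0.341049
104,M,0.371917
105,M,0.405578
40,F,0.000896
41,F,0.000977
42,F,0.001066
43,F,0.001162
44,F,0.001267
45,F,0.001382
46,F,0.001507
47,F,0.001643
48,F,0.001792
49,F,0.001954
50,F,0.002131
51,F,0.002324
52,F,0.002534
53,F,0.002764
54,F,0.003014
55,F,0.003287
56,F,0.003584
57,F,0.003908
58,F,0.004262
59,F,0.004648
60,F,0.005069
61,F,0.005527
62,F,0.006028
63,F,0.006573
64,F,0.007168
65,F,0.007817
66,F,0.008524
67,F,0.009296
68,F,0.010137
69,F,0.011055
70,F,0.012055
71,F,0.013146
72,F,0.014336
73,F,0.015634
74,F,0.017048
75,F,0.018591
76,F,0.020274
77,F,0.022109
78,F,0.02411
79,F,0.026292
80,F,0.028672
81,F,0.031267
82,F,0.034097
83,F,0.037183
84,F,0.040548
85,F,0.044218
86,F,0.04822
87,F,0.052585
88,F,0.057344
89,F,0.062534
90,F,0.068194
91,F,0.074366
92,F,0.081097
93,F,0.088437
94,F,0.096441
95,F,0.105169
96,F,0.114688
97,F,0.125068
98,F,0.136388
99,F,0.148732
100,F,0.162193
101,F,0.176873
102,F,0.192881
103,F,0.210339
104,F,0.229376
105,F,0.250136
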