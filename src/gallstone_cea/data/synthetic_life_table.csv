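# Synthetic Gompertz life table (ONS-style layout: age, sex, annual death probability qx).
# Generated fixture; not real national statistics.
age,sex,qx
40,F,0.000441
41,F,0.000488
42,F,0.000539
43,F,0.000596
44,F,0.000659
45,F,0.000728
46,F,0.000804
47,F,0.000889
48,F,0.000982
49,F,0.001086
50,F,0.0012
51,F,0.001326
52,F,0.001466
53,F,0.00162
54,F,0.00179
55,F,0.001978
56,F,0.002187
57,F,0.002417
58,F,0.002671
59,F,0.002952
60,F,0.003262
61,F,0.003605
62,F,0.003984
63,F,0.004403
64,F,0.004866
65,F,0.005378
66,F,0.005944
67,F,0.006569
68,F,0.00726
69,F,0.008023
70,F,0.008867
71,F,0.009799
72,F,0.01083
73,F,0.011969
74,F,0.013228
75,F,0.014619
76,F,0.016156
77,F,0.017856
78,F,0.019734
79,F,0.021809
80,F,0.024103
81,F,0.026638
82,F,0.029439
83,F,0.032535
84,F,0.035957
85,F,0.039739
86,F,0.043918
87,F,0.048537
88,F,0.053641
89,F,0.059283
90,F,0.065518
91,F,0.072408
92,F,0.080024
93,F,0.08844
94,F,0.097741
95,F,0.108021
96,F,0.119381
97,F,0.131937
98,F,0.145813
99,F,0.161148
100,F,0.178096
40,M,0.000699
41,M,0.000772
42,M,0.000854
43,M,0.000944
44,M,0.001043
45,M,0.001152
46,M,0.001274
47,M,0.001408
48,M,0.001556
49,M,0.001719
50,M,0.0019
51,M,0.0021
52,M,0.002321
53,M,0.002565
54,M,0.002834
55,M,0.003133
56,M,0.003462
57,M,0.003826
58,M,0.004229
59,M,0.004673
60,M,0.005165
61,M,0.005708
62,M,0.006308
63,M,0.006972
64,M,0.007705
65,M,0.008515
66,M,0.009411
67,M,0.010401
68,M,0.011494
69,M,0.012703
70,M,0.014039
71,M,0.015516
72,M,0.017148
73,M,0.018951
74,M,0.020944
75,M,0.023147
76,M,0.025581
77,M,0.028271
78,M,0.031245
79,M,0.034531
80,M,0.038163
81,M,0.042176
82,M,0.046612
83,M,0.051514
84,M,0.056932
85,M,0.062919
86,M,0.069537
87,M,0.07685
88,M,0.084932
89,M,0.093865
90,M,0.103736
91,M,0.114647
92,M,0.126704
93,M,0.14003
94,M,0.154757
95,M,0.171033
96,M,0.18902
97,M,0.2089
98,M,0.23087
99,M,0.255151
100,M,0.281985
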