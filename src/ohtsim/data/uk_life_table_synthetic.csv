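age,qx
35,0.00097344
36,0.00103905
37,0.00111105
38,0.00119007
39,0.00127678
40,0.00137193
41,0.00147635
42,0.00159093
43,0.00171666
44,0.00185462
45,0.00200602
46,0.00217214
47,0.00235441
48,0.00255442
49,0.00277387
50,0.00301466
51,0.00327884
52,0.00356869
53,0.0038867
54,0.00423558
55,0.00461832
56,0.0050382
57,0.00549879
58,0.00600403
59,0.00655822
60,0.00716606
61,0.00783272
62,0.00856383
63,0.00936558
64,0.01024472
65,0.01120865
66,0.01226544
67,0.01342394
68,0.01469377
69,0.01608548
70,0.01761058
71,0.01928158
72,0.02111218
73,0.02311726
74,0.02531303
75,0.02771712
76,0.03034869
77,0.03322855
78,0.03637924
79,0.03982518
80,0.04359279
81,0.04771059
82,0.05220931
83,0.05712202
84,0.06248424
85,0.06833397
86,0.07471183
87,0.08166104
88,0.08922749
89,0.09745964
90,0.10640849
91,0.11612743
92,0.12667198
93,0.13809948
94,0.15046871
95,0.16383925
96,0.17827083
97,0.19382243
98,0.21055117
99,0.22851107
100,0.24775146
101,0.26831523
102,0.29023677
103,0.31353965
104,0.33823405
105,0.36431399
106,0.39175431
107,0.42050765
108,0.45050135
109,1.0
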