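age	annual_mortality
40	0.001826835240527346
41	0.001988906704408196
42	0.002165356673160071
43	0.002357460765558635
44	0.002566607769535559
45	0.002794309682214073
46	0.00304221264066704
47	0.00331210882241981
48	0.003605949401730783
49	0.003925858655315184
50	0.004274149319487267
51	0.004653339309743134
52	0.005066169923655895
53	0.005515625658678297
54	0.006004955788122659
55	0.006537697851298473
56	0.007117703227626096
57	0.00774916497961081
58	0.008436648165963838
59	0.009185122844014574
60	0.01
61	0.010887170666983987
62	0.011853048513203655
63	0.0129046162087289
64	0.014049475905635938
65	0.015295904196633788
66	0.016652911949458865
67	0.01813030944960157
68	0.019738777322304477
69	0.021489943746552203
70	0.023396468519259913
71	0.025472134577390077
72	0.027731947639642977
73	0.030192244688065688
74	0.03287081207383119
75	0.0357870141010158
76	0.03896193301795215
77	0.042418521428204355
78	0.04618176822299781
79	0.050278879234687504
80	0.05473947391727201
81	0.059595799475825884
82	0.06488296399286712
83	0.07063919023701211
84	0.07690609198878998
85	0.08372897488127265
86	0.09115716393040306
87	0.09924436012285354
88	0.10804902863931264
89	0.11763482151980371
90	0.12807103782663037
91	0.13943312463162866
92	0.151803222449539
93	0.1652707590606266
94	0.1799330960155032
95	0.19589623249595994
96	0.21327557162026903
97	0.23219675473284354
98	0.25279656970962905
99	0.2752239398456846
100	0.29964100047397024
101	0.32622427109859437
102	0.35516593151628484
103	0.386675211151614
104	0.42097990164996907
105	0.45832800366333476
106	0.4989895197340787
107	0.5432584062381289
108	0.5914546984988227
109	0.643926824434624
110	0.7010541234668786
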