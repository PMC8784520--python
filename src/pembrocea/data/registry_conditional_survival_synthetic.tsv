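year	conditional_survival
5	0.7
6	0.75
7	0.8
8	0.84
9	0.87
10	0.9
11	0.92
12	0.93
13	0.94
14	0.95
15	0.95
16	0.95
17	0.95
18	0.95
19	0.95
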