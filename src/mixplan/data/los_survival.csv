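s,I,II,III
0,1,1,1
1,0.99,0.99,0.99
2,0.98,0.98,0.98
3,0.97,0.97,0.97
4,0.95,0.96,0.93
5,0.91,0.94,0.9
6,0.85,0.88,0.83
7,0.77,0.79,0.72
8,0.68,0.7,0.64
9,0.61,0.64,0.63
10,0.54,0.58,0.57
11,0.48,0.51,0.48
12,0.41,0.44,0.46
13,0.34,0.36,0.39
14,0.27,0.29,0.3
15,0.23,0.25,0.27
16,0.2,0.22,0.24
17,0.17,0.19,0.21
18,0.14,0.16,0.17
19,0.12,0.14,0.15
20,0.1,0.12,0.13
21,0.08,0.1,0.1
22,0.07,0.08,0.09
23,0.06,0.07,0.07
24,0.05,0.05,0.06
25,0.04,0.04,0.05
26,0.03,0.03,0.04
27,0.02,0.02,0.03
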