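months,survival_percent
0,100.00
1,94.03
2,88.01
3,82.40
6,69.23
9,58.35
12,50.67
18,39.76
24,31.43
36,24.12
48,22.01
72,20.47
96,20.10
120,19.45
144,19.98
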