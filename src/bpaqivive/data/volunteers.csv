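individual,bw_kg
1,94
2,69
3,118
4,72
5,86
6,61
7,91
8,75
9,73
10,68
11,102
12,95
13,68
14,79
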