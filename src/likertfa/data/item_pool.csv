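item_id,b1,b2,b3,b4
1,13,21,29,36
2,16,24,33,41
3,18,28,36,46
4,21,31,38,48
5,24,34,42,53
6,27,38,46,56
7,31,41,48,59
8,34,45,55,64
9,36,48,57,66
10,41,51,61,69
11,45,54,64,73
12,48,57,66,76
13,53,62,71,79
14,56,66,75,83
15,61,70,79,86
16,18,29,41,56
17,24,38,51,62
18,31,44,56,71
19,38,51,63,77
20,41,54,68,83
21,25,41,54,66
22,26,46,64,81
23,21,46,66,83
24,25,51,71,81
25,24,44,65,84
26,19,26,53,82
27,21,38,51,59
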