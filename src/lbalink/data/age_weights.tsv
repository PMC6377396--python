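age	weight
0	51
1	51
2	41
3	44
4	56
5	70
6	73
7	82
8	91
9	106
10	123
11	119
12	137
13	140
14	172
15	179
16	205
17	197
18	201
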