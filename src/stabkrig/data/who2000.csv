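age_band,weight
0-4,8.86
5-9,8.69
10-14,8.60
15-19,8.47
20-24,8.22
25-29,7.93
30-34,7.61
35-39,7.15
40-44,6.59
45-49,6.04
50-54,5.37
55-59,4.55
60-64,3.72
65-69,2.96
70-74,2.21
75-79,1.52
80-84,0.91
85+,0.63
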