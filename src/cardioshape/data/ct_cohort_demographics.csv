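patient,sex,age,weight_kg
01,M,57,66
02,M,49,101
03,M,37,95
04,M,39,92
05,F,59,60
06,M,54,80
07,F,50,95
08,M,47,
09,M,67,73
10,M,47,79
11,M,56,146
12,M,57,72
13,M,49,90
14,F,41,90
15,F,48,85
16,M,60,86
17,M,55,74
18,F,50,76
19,F,47,
20,M,43,78
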