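patient,gender,age_years,duration_months,updrs,hy
1,F,60,24,11,1.5
2,M,57,24,36,2
3,F,68,9,17,2
4,F,48,12,22,1
5,F,72,18,23,1
6,F,50,6,18,1
7,F,54,36,33,1.5
8,M,52,36,26,2
9,F,47,12,32,2
10,M,38,12,27,1.5
11,M,54,12,26,1
12,M,65,6,27,2
13,F,44,12,9,1
14,F,71,4,23,1
15,F,62,6,11,1
16,M,58,10,39,2
17,M,59,12,33,2
18,F,47,24,50,2
19,M,57,24,12,1
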