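run,X1,X2,X3,Y,Y_sd
1,-1,-1,0,5.32,0.11
2,-1,1,0,5.63,0.13
3,1,-1,0,5.49,0.17
4,1,1,0,6.04,0.14
5,0,-1,-1,4.96,0.22
6,0,-1,1,4.99,0.14
7,0,1,-1,5.49,0.15
8,0,1,1,5.56,0.06
9,-1,0,-1,5.40,0.09
10,1,0,-1,5.29,0.17
11,-1,0,1,5.29,0.18
12,1,0,1,5.38,0.08
13,0,0,0,6.15,0.05
14,0,0,0,6.24,0.03
15,0,0,0,6.18,0.12
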