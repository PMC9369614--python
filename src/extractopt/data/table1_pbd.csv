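run,X1,X2,X3,X4,X5,X6,X7,X8,Y,Y_sd
1,-1,-1,-1,1,1,1,-1,1,3.65,0.33
2,-1,-1,-1,-1,-1,-1,-1,-1,4.29,0.14
3,1,1,-1,1,1,-1,1,-1,4.26,0.24
4,-1,1,-1,-1,-1,1,1,1,5.41,0.14
5,1,-1,-1,-1,1,1,1,-1,5.87,0.17
6,-1,1,1,-1,1,-1,-1,-1,6.16,0.11
7,1,1,1,-1,1,1,-1,1,5.95,0.14
8,1,1,-1,1,-1,-1,-1,1,5.74,0.14
9,1,-1,1,-1,-1,-1,1,1,4.91,0.35
10,-1,1,1,1,-1,1,1,-1,4.44,0.09
11,-1,-1,1,1,1,-1,1,1,5.39,0.06
12,1,-1,1,1,-1,1,-1,-1,4.76,0.24
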