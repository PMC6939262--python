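id,sire,dam,sex,cohort
A,0,0,m,0
B,0,0,f,0
C,0,0,m,0
D,0,0,f,0
M1,A,B,m,1
F1,A,B,f,1
M2,C,D,m,1
I1,M1,F1,f,2
O1,M1,F1,m,3
O2,M2,F1,f,3
O3,M2,I1,m,3
O4,A,D,f,3
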