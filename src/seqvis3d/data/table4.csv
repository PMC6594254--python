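method,D1,C1,D2,C2,D3,C3,C4,D4,C5,D5
E,0,1,0,1,0,1,0,1,0,1
NN1,1,0,0,0,0,1,1,0,1,0
NN2,1,1,1,1,0,0,0,1,1,1
NN3,0,1,0,1,0,0,0,1,1,1
H1,0,0,1,0,1,1,1,0,1,0
H2,1,1,1,1,1,1,0,1,1,0
H3,0,1,0,0,0,0,1,1,1,1
1-HH1,1,0,1,0,1,1,1,0,0,0
1-HH2,0,1,1,0,0,0,0,1,1,0
1-HH3,1,1,0,1,0,0,0,0,0,1
2-HH1,1,0,0,0,1,1,1,1,1,0
2-HH2,1,1,1,1,1,1,1,0,0,1
2-HH3,0,1,0,0,0,0,0,1,0,1
10-HH1,1,0,0,1,1,1,1,1,1,1
10-HH2,1,0,0,1,0,0,0,1,0,1
10-HH3,1,1,0,1,0,1,0,1,0,1
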