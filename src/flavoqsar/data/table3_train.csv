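compound_no,observed_pfar,predicted_pfar,residual
1,-1.26,-1.20,-0.06
2,-1.67,-1.54,-0.13
3,-0.49,-0.63,0.14
4,-0.48,-0.34,-0.13
5,-0.45,-0.52,0.07
6,-1.46,-1.39,-0.07
7,-0.46,-0.47,0.01
8,-0.45,-0.42,-0.03
9,-0.36,-0.16,-0.20
10,-1.16,-1.38,0.22
11,-0.18,-0.27,0.09
12,-0.69,-0.60,-0.09
13,0.22,0.12,0.10
14,0.15,0.03,0.12
15,0.15,-0.09,0.25
16,0.10,0.32,-0.22
17,0.30,0.21,0.10
18,0.22,0.25,-0.03
19,0.10,0.30,-0.20
20,-0.38,-0.34,-0.04
21,-1.56,-1.34,-0.22
22,0.01,-0.44,0.45
23,0.24,0.36,-0.13
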