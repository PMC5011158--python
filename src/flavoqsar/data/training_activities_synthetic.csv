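compound_no,id,FAR,pFAR
1,flavone,18.20,-1.26
2,flavanone,46.77,-1.67
3,chrysin,3.09,-0.49
4,apigenin,3.02,-0.48
5,luteolin,2.82,-0.45
6,galangin,28.84,-1.46
7,kaempferol,2.88,-0.46
8,quercetin,2.82,-0.45
9,myricetin,2.29,-0.36
10,fisetin,14.45,-1.16
11,morin,1.51,-0.18
12,naringenin,4.90,-0.69
13,eriodictyol,0.60,0.22
14,taxifolin,0.71,0.15
15,catechin,0.71,0.15
16,epicatechin,0.79,0.10
17,genistein,0.50,0.30
18,daidzein,0.60,0.22
19,biochanin_A,0.79,0.10
20,naringin,2.40,-0.38
21,hesperetin,36.31,-1.56
22,baicalein,0.98,0.01
23,tangeretin,0.58,0.24
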