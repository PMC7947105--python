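Name,pIC50_exp,pIC50_pred,residual,set
1,4.9115,4.9067,0.0048,train
2,4.0000,4.0070,-0.0070,train
5,4.4743,4.4012,0.0731,train
6,4.2248,4.3582,-0.1334,test
7,4.5452,4.4373,0.1078,test
8,4.6548,4.6486,0.0062,train
9,4.3706,4.4557,-0.0852,test
10,4.6185,4.5560,0.0625,test
11,4.5424,4.5056,0.0368,train
12,4.0000,3.8942,0.1058,test
13,4.1748,4.1651,0.0097,train
14,4.0000,3.9974,0.0026,train
15,4.0000,4.0032,-0.0032,train
16,4.0000,3.9531,0.0469,train
17,4.1392,4.2393,-0.1002,train
18,4.1395,3.9735,0.1660,test
19,4.1914,4.1859,0.0055,train
20,4.0000,3.7604,0.2396,test
21,4.8573,4.8269,0.0304,train
22,5.4750,5.5102,-0.0353,train
23,5.3344,5.3283,0.0061,train
24,4.0786,4.0943,-0.0156,train
25,4.0232,4.0193,0.0039,test
26,4.1232,4.1841,-0.0609,train
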