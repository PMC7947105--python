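Name,ATSC3c,MATS5p,minHBint5,ETA_Shape_P,pIC50_exp,pIC50_pred
10,0.1896,-0.2790,0.0000,0.2778,4.6185,4.5560
12,0.0761,-0.0651,0.0000,0.1471,4.0000,3.8942
18,0.0244,-0.2706,0.0000,0.1471,4.1395,3.9735
20,0.0417,-0.2081,1.6445,0.1887,4.0000,3.7604
25,0.0817,-0.1618,0.0000,0.1613,4.0232,4.0193
6,0.1136,-0.2585,0.0000,0.2672,4.2248,4.3582
7,0.1352,-0.3068,0.0000,0.2609,4.5452,4.4373
9,0.1967,-0.3069,0.0000,0.1961,4.3706,4.4557
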