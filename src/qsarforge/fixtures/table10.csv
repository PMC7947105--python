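Name,pIC50_exp,qsar_pred,qsar_pct_error,elm_sine_pred,elm_sine_pct_error,elm_sig_pred,elm_sig_pct_error
1,4.9115,4.9067,0.0977,4.9385,0.5493,4.8448,1.3589
2,4.0000,4.0070,0.1750,3.9999,0.0019,3.9996,0.0106
5,4.4743,4.4012,1.6338,4.4120,1.3919,4.3969,1.7295
6,4.2248,4.3582,3.1575,4.3714,3.4692,4.3472,2.8982
7,4.5452,4.4373,2.3739,4.4601,1.8727,4.4277,2.5852
8,4.6548,4.6486,0.1332,4.6534,0.0291,4.6555,0.0148
9,4.3706,4.4557,1.9471,4.5178,3.3690,4.4533,1.8923
10,4.6185,4.5560,1.3533,4.5696,1.0597,4.5461,1.5679
11,4.5424,4.5056,0.8101,4.5379,0.0996,4.4983,0.9703
12,4.0000,3.8942,2.6450,3.9358,1.6052,3.9817,0.4565
13,4.1748,4.1651,0.2323,4.2014,0.6378,4.1751,0.0065
14,4.0000,3.9974,0.0650,4.0626,1.5646,4.0472,1.1800
15,4.0000,4.0032,0.0800,4.0157,0.3930,4.0405,1.0118
16,4.0000,3.9531,1.1725,3.9822,0.4460,3.9595,1.0130
17,4.1392,4.2393,2.4183,4.2094,1.6951,4.2496,2.6660
18,4.1395,3.9735,4.0101,3.9754,3.9637,4.0114,3.0952
19,4.1914,4.1859,0.1312,4.1513,0.9557,4.1897,0.0408
20,4.0000,3.7604,5.9900,3.9952,0.1190,4.0102,0.2543
21,4.8573,4.8269,0.6259,4.8418,0.3188,4.8159,0.8514
22,5.4750,5.5102,0.6429,5.4205,0.9955,5.4652,0.1781
23,5.3344,5.3283,0.1144,5.3572,0.4279,5.3681,0.6321
24,4.0786,4.0943,0.3849,4.0783,0.0063,4.1023,0.5817
25,4.0232,4.0193,0.0969,4.1032,1.9879,4.0618,0.9585
26,4.1232,4.1841,1.4770,4.1819,1.4232,4.1691,1.1120
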