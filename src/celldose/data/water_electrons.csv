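# material: water
# density_g_cm3: 1.0
energy_keV,stopping_keV_per_um
0.1,26.8151
0.108678,26.0453
0.11811,25.2976
0.12836,24.5714
0.139499,23.866
0.151606,23.1809
0.164763,22.5154
0.179061,21.869
0.194601,21.2412
0.211489,20.6314
0.229843,20.0391
0.24979,19.4639
0.271467,18.9051
0.295026,18.3624
0.32063,17.8352
0.348455,17.3232
0.378695,16.8259
0.41156,16.3429
0.447276,15.8737
0.486093,15.418
0.528278,14.9754
0.574123,14.5455
0.623948,14.1279
0.678097,13.7223
0.736944,13.3284
0.800899,12.9458
0.870404,12.5741
0.945941,12.2131
1.02803,11.7695
1.11725,11.1575
1.21421,10.5685
1.31958,10.0028
1.4341,9.4604
1.55856,8.94124
1.69381,8.44504
1.84081,7.97147
2.00056,7.52008
2.17418,7.09035
2.36286,6.68171
2.56792,6.29354
2.79077,5.92518
3.03297,5.57595
3.29618,5.24515
3.58223,4.93207
3.89311,4.636
4.23097,4.35623
4.59815,4.09204
4.99719,3.84274
5.43087,3.60765
5.90218,3.38608
6.41439,3.1774
6.97106,2.98095
7.57603,2.79613
8.23351,2.62233
8.94804,2.45899
9.72458,2.30554
10.5685,2.16146
11.4857,2.02624
12.4825,1.89939
13.5657,1.78044
14.743,1.66895
16.0225,1.56449
17.413,1.46666
18.9241,1.37507
20.5664,1.28936
22.3513,1.20919
24.291,1.13422
26.3991,1.06414
28.6901,0.998659
31.1799,0.937501
33.8858,0.8804
36.8265,0.827108
40.0225,0.777391
43.4958,0.731028
47.2705,0.68781
51.3728,0.647542
55.8311,0.610039
60.6763,0.575127
65.9421,0.542644
71.6648,0.512436
77.8841,0.48436
84.6432,0.45828
91.9888,0.434071
99.9719,0.411613
108.648,0.390795
118.077,0.371513
128.324,0.35367
139.46,0.337175
151.563,0.321942
164.716,0.307892
179.011,0.294949
194.546,0.283045
211.43,0.272114
229.778,0.262095
249.719,0.252931
271.391,0.24457
294.943,0.23696
320.54,0.230055
348.357,0.223813
378.589,0.218191
411.444,0.21315
447.151,0.208656
485.956,0.204673
528.129,0.20117
573.962,0.198116
623.773,0.195482
677.906,0.193241
736.737,0.191368
800.674,0.189837
870.16,0.188625
945.675,0.18771
1027.74,0.187071
1116.94,0.186688
1213.87,0.186541
1319.21,0.186613
1433.7,0.186886
1558.12,0.187344
1693.34,0.187972
1840.29,0.188754
2000,0.189679
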