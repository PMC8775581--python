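# material: gold
# density_g_cm3: 19.3
energy_keV,stopping_keV_per_um
0.1,205.722
0.108678,202.326
0.11811,198.986
0.12836,195.702
0.139499,192.471
0.151606,189.294
0.164763,186.17
0.179061,183.097
0.194601,180.074
0.211489,177.102
0.229843,174.179
0.24979,171.303
0.271467,168.476
0.295026,165.695
0.32063,162.96
0.348455,160.27
0.378695,157.624
0.41156,155.022
0.447276,152.463
0.486093,149.947
0.528278,147.472
0.574123,145.037
0.623948,142.643
0.678097,140.289
0.736944,137.973
0.800899,135.695
0.870404,133.456
0.945941,131.253
1.02803,126.857
1.11725,118.39
1.21421,110.489
1.31958,103.114
1.4341,96.2321
1.55856,89.8092
1.69381,83.8151
1.84081,78.221
2.00056,73.0003
2.17418,68.128
2.36286,63.581
2.56792,59.3374
2.79077,55.377
3.03297,51.681
3.29618,48.2316
3.58223,45.0125
3.89311,42.0082
4.23097,39.2045
4.59815,36.5879
4.99719,34.1459
5.43087,31.8669
5.90218,29.74
6.41439,27.755
6.97106,25.9026
7.57603,24.1738
8.23351,22.5603
8.94804,21.0546
9.72458,19.6493
10.5685,18.3379
11.4857,17.114
12.4825,15.9717
13.5657,14.9057
14.743,13.9109
16.0225,12.9824
17.413,12.1159
18.9241,11.3073
20.5664,10.6046
22.3513,10.0416
24.291,9.50675
26.3991,8.99933
28.6901,8.51849
31.1799,8.06332
33.8858,7.63293
36.8265,7.22638
40.0225,6.84274
43.4958,6.48108
47.2705,6.14046
51.3728,5.81997
55.8311,5.51872
60.6763,5.23581
65.9421,4.97038
71.6648,4.72161
77.8841,4.48869
84.6432,4.27083
91.9888,4.06728
99.9719,3.87733
108.648,3.70027
118.077,3.53544
128.324,3.38221
139.46,3.23998
151.563,3.10816
164.716,2.98622
179.011,2.87363
194.546,2.76989
211.43,2.67455
229.778,2.58714
249.719,2.50726
271.391,2.43449
294.943,2.36847
320.54,2.30884
348.357,2.25524
378.589,2.20737
411.444,2.16491
447.151,2.12756
485.956,2.09506
528.129,2.06712
573.962,2.04351
623.773,2.02396
677.906,2.00825
736.737,1.99615
800.674,1.98745
870.16,1.98193
945.675,1.97939
1027.74,1.97965
1116.94,1.9825
1213.87,1.98778
1319.21,1.99532
1433.7,2.00493
1558.12,2.01648
1693.34,2.0298
1840.29,2.04475
2000,2.06121
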