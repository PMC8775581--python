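# material: water
# density_g_cm3: 1.0
energy_keV,mu_pe_per_um,mu_compton_per_um,mu_total_per_um
1,0.4944,2.21518e-05,0.494422
1.08071,0.391701,2.21449e-05,0.391723
1.16793,0.310335,2.21374e-05,0.310358
1.26219,0.245871,2.21293e-05,0.245893
1.36405,0.194798,2.21205e-05,0.19482
1.47414,0.154334,2.21111e-05,0.154356
1.59312,0.122275,2.21009e-05,0.122297
1.72169,0.0968754,2.20899e-05,0.0968974
1.86064,0.076752,2.2078e-05,0.0767741
2.01081,0.0608088,2.20652e-05,0.0608308
2.17309,0.0481773,2.20514e-05,0.0481994
2.34848,0.0381697,2.20364e-05,0.0381918
2.53802,0.0302409,2.20204e-05,0.030263
2.74285,0.0239592,2.2003e-05,0.0239812
2.96422,0.0189823,2.19843e-05,0.0190043
3.20345,0.0150392,2.19641e-05,0.0150612
3.46199,0.0119152,2.19423e-05,0.0119371
3.7414,0.00944012,2.19189e-05,0.00946204
4.04335,0.00747918,2.18936e-05,0.00750107
4.36968,0.00592557,2.18664e-05,0.00594744
4.72234,0.00469469,2.18371e-05,0.00471652
5.10347,0.00371949,2.18055e-05,0.00374129
5.51535,0.00294686,2.17715e-05,0.00296863
5.96048,0.00233473,2.17349e-05,0.00235646
6.44153,0.00184975,2.16956e-05,0.00187144
6.9614,0.00146551,2.16533e-05,0.00148716
7.52323,0.00116109,2.16078e-05,0.0011827
8.13041,0.000919902,2.15589e-05,0.000941461
8.78659,0.000728816,2.15064e-05,0.000750322
9.49572,0.000577423,2.14501e-05,0.000598873
10.2621,0.000457478,2.13896e-05,0.000478868
11.0903,0.000362449,2.13248e-05,0.000383774
11.9854,0.00028716,2.12553e-05,0.000308415
12.9527,0.00022751,2.11808e-05,0.00024869
13.998,0.00018025,2.11011e-05,0.000201352
15.1278,0.000142808,2.10159e-05,0.000163824
16.3487,0.000113143,2.09249e-05,0.000134068
17.6681,8.96407e-05,2.08276e-05,0.000110468
19.0941,7.10202e-05,2.07238e-05,9.1744e-05
20.6351,5.62676e-05,2.06132e-05,7.68808e-05
22.3005,4.45794e-05,2.04955e-05,6.50749e-05
24.1003,3.53192e-05,2.03702e-05,5.56894e-05
26.0454,2.79826e-05,2.02371e-05,4.82197e-05
28.1474,2.21699e-05,2.00959e-05,4.22658e-05
30.4191,1.75647e-05,1.99462e-05,3.75109e-05
32.8741,1.39161e-05,1.97878e-05,3.37038e-05
35.5273,1.10254e-05,1.96203e-05,3.06457e-05
38.3946,8.73513e-06,1.94436e-05,2.81788e-05
41.4933,6.92063e-06,1.92575e-05,2.61781e-05
44.842,5.48305e-06,1.90617e-05,2.45448e-05
48.4611,4.34409e-06,1.88561e-05,2.32002e-05
52.3722,3.44172e-06,1.86407e-05,2.20824e-05
56.599,2.72679e-06,1.84154e-05,2.11422e-05
61.167,2.16037e-06,1.81802e-05,2.03406e-05
66.1035,1.71161e-06,1.79352e-05,1.96468e-05
71.4385,1.35607e-06,1.76805e-05,1.90366e-05
77.2041,1.07438e-06,1.74164e-05,1.84908e-05
83.435,8.51204e-07,1.71432e-05,1.79944e-05
90.1688,6.74388e-07,1.68611e-05,1.75355e-05
97.446,5.34301e-07,1.65706e-05,1.71049e-05
105.311,4.23314e-07,1.62723e-05,1.66956e-05
113.81,3.35382e-07,1.59666e-05,1.6302e-05
122.995,2.65715e-07,1.56542e-05,1.59199e-05
132.922,2.10519e-07,1.53357e-05,1.55462e-05
143.649,1.66789e-07,1.50118e-05,1.51786e-05
155.243,1.32143e-07,1.46833e-05,1.48155e-05
167.772,1.04694e-07,1.4351e-05,1.44556e-05
181.312,8.29464e-08,1.40155e-05,1.40984e-05
195.945,6.57164e-08,1.36777e-05,1.37434e-05
211.759,5.20655e-08,1.33384e-05,1.33904e-05
228.85,4.12503e-08,1.29982e-05,1.30395e-05
247.32,3.26816e-08,1.2658e-05,1.26907e-05
267.28,2.58928e-08,1.23183e-05,1.23442e-05
288.851,2.05143e-08,1.19799e-05,1.20005e-05
312.163,1.6253e-08,1.16434e-05,1.16596e-05
337.357,1.28768e-08,1.13092e-05,1.1322e-05
364.584,1.0202e-08,1.09778e-05,1.0988e-05
394.009,8.0828e-09,1.06496e-05,1.06577e-05
425.808,6.4038e-09,1.03252e-05,1.03316e-05
460.173,5.07358e-09,1.00046e-05,1.00097e-05
497.312,4.01967e-09,9.68832e-06,9.69234e-06
537.449,3.18469e-09,9.37648e-06,9.37966e-06
580.825,2.52315e-09,9.06928e-06,9.07181e-06
627.701,1.99903e-09,8.76691e-06,8.76891e-06
678.361,1.58379e-09,8.46949e-06,8.47107e-06
733.109,1.2548e-09,8.17715e-06,8.1784e-06
792.276,9.94144e-10,7.88998e-06,7.89098e-06
856.218,7.87636e-10,7.60809e-06,7.60888e-06
925.32,6.24025e-10,7.33155e-06,7.33218e-06
1000,4.944e-10,7.06045e-06,7.06095e-06
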