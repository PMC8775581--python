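# material: gold
# density_g_cm3: 19.3
energy_keV,mu_pe_per_um,mu_compton_per_um,mu_total_per_um
1,8.98777,0.000308906,8.98808
1.08071,8.59214,0.000308809,8.59245
1.16793,8.21393,0.000308705,8.21424
1.26219,7.85236,0.000308592,7.85267
1.36405,7.50671,0.00030847,7.50702
1.47414,7.17628,0.000308338,7.17659
1.59312,6.86039,0.000308196,6.8607
1.72169,6.5584,0.000308042,6.55871
1.86064,6.26971,0.000307877,6.27002
2.01081,5.99373,0.000307698,5.99404
2.17309,5.72989,0.000307505,5.7302
2.20978,5.67453,0.000307462,5.67484
2.21022,8.23274,0.000307461,8.23305
2.34848,7.11709,0.000307297,7.1174
2.53802,5.9075,0.000307073,5.90781
2.74285,4.90349,0.000306831,4.90379
2.96422,4.07011,0.00030657,4.07042
3.20345,3.37837,0.000306288,3.37868
3.46199,2.8042,0.000305985,2.8045
3.7414,2.32761,0.000305658,2.32791
4.04335,1.93202,0.000305305,1.93232
4.36968,1.60366,0.000304926,1.60396
4.72234,1.33111,0.000304517,1.33141
5.10347,1.10488,0.000304077,1.10518
5.51535,0.917096,0.000303603,0.9174
5.96048,0.76123,0.000303093,0.761533
6.44153,0.631855,0.000302544,0.632157
6.9614,0.524467,0.000301954,0.524769
7.52323,0.435331,0.00030132,0.435632
8.13041,0.361344,0.000300638,0.361644
8.78659,0.299931,0.000299906,0.300231
9.49572,0.248956,0.00029912,0.249255
10.2621,0.206645,0.000298277,0.206943
11.0903,0.171524,0.000297373,0.171821
11.9188,0.144288,0.000296475,0.144585
11.9212,0.378188,0.000296473,0.378485
11.9854,0.373285,0.000296404,0.373582
12.9527,0.309123,0.000295366,0.309418
13.998,0.255989,0.000294255,0.256283
15.1278,0.211988,0.000293066,0.212281
16.3487,0.17555,0.000291796,0.175842
17.6681,0.145375,0.00029044,0.145666
19.0941,0.120387,0.000288993,0.120676
20.6351,0.0996943,0.000287451,0.0999817
22.3005,0.0825582,0.000285808,0.082844
24.1003,0.0683676,0.000284062,0.0686516
26.0454,0.0566161,0.000282206,0.0568983
28.1474,0.0468846,0.000280236,0.0471648
30.4191,0.0388257,0.000278149,0.0391039
32.8741,0.0321521,0.000275939,0.0324281
35.5273,0.0266256,0.000273605,0.0268992
38.3946,0.022049,0.000271141,0.0223202
41.4933,0.0182591,0.000268545,0.0185276
44.842,0.0151206,0.000265815,0.0153864
48.4611,0.0125216,0.000262948,0.0127845
52.3722,0.0103693,0.000259944,0.0106292
56.599,0.00858695,0.000256802,0.00884375
61.167,0.00711097,0.000253522,0.00736449
66.1035,0.00588869,0.000250105,0.00613879
71.4385,0.0048765,0.000246554,0.00512306
77.2041,0.0040383,0.000242871,0.00428117
80.6919,0.00362717,0.000240717,0.00386788
80.7081,0.0171718,0.000240707,0.0174126
83.435,0.0155426,0.000239061,0.0157816
90.1688,0.012314,0.000235127,0.0125491
97.446,0.00975609,0.000231077,0.00998717
105.311,0.00772951,0.000226916,0.00795643
113.81,0.00612391,0.000222654,0.00634656
122.995,0.00485182,0.000218297,0.00507012
132.922,0.00384398,0.000213856,0.00405784
143.649,0.00304549,0.000209339,0.00325483
155.243,0.00241287,0.000204758,0.00261763
167.772,0.00191166,0.000200123,0.00211178
181.312,0.00151456,0.000195445,0.00171001
195.945,0.00119995,0.000190735,0.00139069
211.759,0.000950692,0.000186003,0.00113669
228.85,0.00075321,0.00018126,0.00093447
247.32,0.00059675,0.000176515,0.000773265
267.28,0.000472791,0.000171779,0.00064457
288.851,0.000374581,0.00016706,0.000541641
312.163,0.000296771,0.000162366,0.000459138
337.357,0.000235125,0.000157706,0.00039283
364.584,0.000186284,0.000153085,0.000339368
394.009,0.000147588,0.000148509,0.000296097
425.808,0.00011693,0.000143984,0.000260914
460.173,9.26411e-05,0.000139514,0.000232155
497.312,7.33973e-05,0.000135103,0.000208501
537.449,5.81509e-05,0.000130755,0.000188905
580.825,4.60716e-05,0.000126471,0.000172542
627.701,3.65014e-05,0.000122254,0.000158756
678.361,2.89192e-05,0.000118107,0.000147026
733.109,2.2912e-05,0.00011403,0.000136942
792.276,1.81526e-05,0.000110025,0.000128178
856.218,1.43819e-05,0.000106094,0.000120476
925.32,1.13944e-05,0.000102238,0.000113633
1000,9.02751e-06,9.84577e-05,0.000107485
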