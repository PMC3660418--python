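unit_id,d0_um,d1_um,d2_um,S1_1e4um2,S2_1e4um2,V1_nL,V2_nL
1,88.6,83.6,67.2,8.79,6.95,0.833,0.607
2,87.7,73.7,68.8,8.10,8.95,0.701,0.710
3,76.2,69.1,52.8,4.20,2.73,0.335,0.206
4,101,69.0,57.0,4.67,3.55,0.370,0.265
5,56.0,50.2,46.6,3.85,2.39,0.246,0.121
6,52.5,46.1,41.4,3.41,1.51,0.197,0.0634
7,60.4,45.0,29.0,1.62,0.851,0.0852,0.0305
8,123,92.0,64.8,7.52,4.51,0.646,0.396
9,102,80.0,63.0,5.24,5.17,0.489,0.437
10,73.3,77.2,61.9,4.11,3.07,0.319,0.202
11,97.0,75.0,73.6,3.77,4.67,0.340,0.432
12,80.1,70.0,62.3,3.23,3.25,0.217,0.242
13,86.1,83.0,60.0,9.77,4.12,0.920,0.308
14,98.0,73.8,64.5,7.75,3.90,0.680,0.284
15,70.3,55.7,42.7,4.35,3.34,0.364,0.279
16,67.6,52.2,44.8,2.01,3.43,0.115,0.205
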