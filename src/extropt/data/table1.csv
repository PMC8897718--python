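run,X1_power_W,X2_temp_C,X3_ratio_mL_per_g,X4_time_min,yield_pct
1,200,50,20,30,6.95
2,400,50,20,30,7.03
3,200,70,20,30,7.24
4,400,70,20,30,7.21
5,300,60,15,20,6.93
6,300,60,25,20,7.16
7,300,60,15,40,7.11
8,300,60,25,40,7.21
9,200,60,20,20,7.13
10,400,60,20,20,6.89
11,200,60,20,40,6.99
12,400,60,20,40,7.28
13,300,50,15,30,6.83
14,300,70,15,30,7.38
15,300,50,25,30,7.26
16,300,70,25,30,7.23
17,200,60,15,30,6.92
18,400,60,15,30,7.06
19,200,60,25,30,7.11
20,400,60,25,30,7.19
21,300,50,20,20,6.97
22,300,70,20,20,7.16
23,300,50,20,40,6.93
24,300,70,20,40,7.31
25,300,60,20,30,7.42
26,300,60,20,30,7.39
27,300,60,20,30,7.31
28,300,60,20,30,7.50
29,300,60,20,30,7.16
30,300,60,20,30,7.24
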