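# CTDIvol -> SSDE conversion factors, 32-cm body phantom,
# indexed by the sum of patient AP and LAT dimensions (cm).
# Sampled from the AAPM Report 204 exponential parameterisation
# f = 3.704369 * exp(-0.03671937 * (sum/2)).
sum_cm,factor
12,2.9719
13,2.9178
14,2.8647
15,2.8126
16,2.7615
17,2.7112
18,2.6619
19,2.6135
20,2.5659
21,2.5192
22,2.4734
23,2.4284
24,2.3842
25,2.3409
26,2.2983
27,2.2565
28,2.2154
29,2.1751
30,2.1355
31,2.0967
32,2.0586
33,2.0211
34,1.9843
35,1.9482
36,1.9128
37,1.8780
38,1.8438
39,1.8103
40,1.7774
41,1.7450
42,1.7133
43,1.6821
44,1.6515
45,1.6215
46,1.5920
47,1.5630
48,1.5346
49,1.5066
50,1.4792
51,1.4523
52,1.4259
53,1.4000
54,1.3745
55,1.3495
56,1.3249
57,1.3008
58,1.2772
59,1.2539
60,1.2311
61,1.2087
62,1.1867
63,1.1652
64,1.1440
65,1.1231
66,1.1027
67,1.0827
68,1.0630
69,1.0436
70,1.0246
71,1.0060
72,0.9877
73,0.9697
74,0.9521
75,0.9348
76,0.9178
77,0.9011
78,0.8847
79,0.8686
80,0.8528
81,0.8373
82,0.8220
83,0.8071
84,0.7924
85,0.7780
86,0.7638
87,0.7499
88,0.7363
89,0.7229
90,0.7097
91,0.6968
92,0.6842
93,0.6717
94,0.6595
95,0.6475
96,0.6357
97,0.6241
98,0.6128
99,0.6016
100,0.5907
101,0.5799
102,0.5694
103,0.5590
104,0.5489
105,0.5389
106,0.5291
107,0.5195
108,0.5100
109,0.5007
110,0.4916
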