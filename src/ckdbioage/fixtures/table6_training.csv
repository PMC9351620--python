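# 133-patient CKD training cohort: chronological age, CKD stage,
# composite biological-age index and estimated biological age
# (published values).
no,ca,ckd_stage,ba_index,ba
1,64,4,0.524,69
2,60,4,0.6699,66
3,48,3,0.5611,53
4,65,4,0.5914,71
5,67,4,0.7351,74
6,63,5,0.9507,72
7,60,5,0.7954,67
8,59,3,0.7737,66
9,70,4,0.9129,79
10,66,3,0.9264,75
11,61,3,0.7143,68
12,82,4,0.7948,89
13,57,5,0.8876,65
14,48,2,0.6292,54
15,67,4,0.6962,74
16,43,3,0.8947,51
17,81,5,1.0,90
18,55,3,0.3852,59
19,63,3,0.7392,70
20,63,3,0.757,70
21,68,4,0.9649,77
22,60,4,0.7578,67
23,67,4,0.7214,74
24,58,5,0.968,67
25,58,4,0.749,65
26,56,4,0.8093,64
27,43,4,0.9002,51
28,62,4,0.8951,70
29,75,3,0.8297,83
30,55,4,0.9661,64
31,62,4,0.6336,68
32,63,4,0.7361,70
33,72,4,0.7405,79
34,76,4,0.8005,84
35,43,4,0.677,49
36,59,3,0.9323,68
37,72,3,0.6619,78
38,64,4,0.6324,70
39,72,4,0.8376,80
40,46,3,0.704,53
41,75,4,0.7902,82
42,69,3,0.6955,76
43,66,4,0.6984,73
44,68,2,0.4181,72
45,64,3,0.6099,70
46,55,4,0.9653,64
47,63,4,0.7009,70
48,63,3,0.3643,66
49,69,4,0.8109,77
50,69,3,0.807,77
51,76,4,0.6379,82
52,68,4,0.7109,75
53,65,3,0.5285,70
54,65,3,0.8299,73
55,59,3,0.7763,66
56,69,4,0.8914,77
57,76,3,0.9309,85
58,69,4,0.7874,76
59,63,5,0.6161,69
60,48,3,0.6912,55
61,59,5,0.972,68
62,53,2,0.4258,57
63,56,2,0.6054,62
64,65,2,0.7176,72
65,69,4,0.9307,78
66,58,3,0.6751,64
67,57,3,0.66,63
68,70,3,0.8971,78
69,56,3,0.9104,65
70,64,5,0.9575,73
71,65,3,0.9392,74
72,37,3,0.6988,44
73,53,3,0.6813,59
74,81,3,0.838,89
75,36,2,0.6562,42
76,73,4,0.8726,81
77,68,3,0.6789,74
78,70,4,0.8573,78
79,74,3,0.6681,80
80,48,4,0.9191,57
81,64,3,0.8854,72
82,61,4,0.7756,68
83,37,4,0.6919,44
84,65,4,0.7499,72
85,78,3,0.7795,85
86,77,4,0.9145,86
87,69,4,0.8449,77
88,58,3,0.7076,65
89,63,3,0.7245,70
90,63,3,0.9308,72
91,70,3,0.7933,77
92,74,4,0.817,82
93,53,4,0.6986,60
94,67,4,0.766,74
95,71,3,0.7973,79
96,53,5,0.6726,59
97,52,3,0.6456,58
98,60,3,0.897,68
99,73,3,0.7774,80
100,61,5,0.5983,67
101,66,3,0.5996,72
102,71,4,0.9006,79
103,78,3,0.6414,84
104,64,4,0.6862,70
105,50,3,0.6637,56
106,68,3,0.7547,75
107,53,3,0.8595,61
108,75,3,0.7372,82
109,63,3,0.9176,72
110,58,4,0.676,64
111,82,4,0.9827,91
112,68,3,0.7254,75
113,67,3,0.705,74
114,61,5,0.8571,69
115,51,4,0.7512,58
116,54,5,0.7234,61
117,72,3,0.5938,78
118,67,3,0.7171,74
119,77,4,0.8781,85
120,60,3,0.6174,66
121,64,3,0.7517,71
122,62,3,0.5667,67
123,82,4,0.9089,91
124,74,4,0.8258,82
125,74,4,0.862,82
126,62,3,0.7566,69
127,63,4,0.7086,70
128,67,3,0.7509,74
129,59,3,0.6114,65
130,71,5,0.9078,80
131,71,4,0.6842,77
132,65,3,0.6418,71
133,71,3,0.9161,80
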