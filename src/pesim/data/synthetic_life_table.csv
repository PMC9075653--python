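age,remaining_life_expectancy
0,75.0
1,74.28
2,73.56
3,72.85
4,72.14
5,71.43
6,70.72
7,70.02
8,69.32
9,68.62
10,67.92
11,67.23
12,66.53
13,65.84
14,65.16
15,64.47
16,63.79
17,63.11
18,62.43
19,61.75
20,61.08
21,60.41
22,59.74
23,59.07
24,58.41
25,57.75
26,57.09
27,56.43
28,55.78
29,55.13
30,54.48
31,53.83
32,53.19
33,52.55
34,51.91
35,51.27
36,50.64
37,50.0
38,49.37
39,48.75
40,48.12
41,47.5
42,46.88
43,46.26
44,45.64
45,45.03
46,44.42
47,43.81
48,43.2
49,42.6
50,42.0
51,41.4
52,40.8
53,40.21
54,39.62
55,39.03
56,38.44
57,37.86
58,37.28
59,36.7
60,36.12
61,35.55
62,34.97
63,34.4
64,33.84
65,33.27
66,32.71
67,32.15
68,31.59
69,31.03
70,30.48
71,29.93
72,29.38
73,28.83
74,28.29
75,27.75
76,27.21
77,26.67
78,26.14
79,25.61
80,25.08
81,24.55
82,24.03
83,23.51
84,22.99
85,22.47
86,21.96
87,21.44
88,20.93
89,20.43
90,19.92
91,19.42
92,18.92
93,18.42
94,17.92
95,17.43
96,16.94
97,16.45
98,15.96
99,15.48
100,15.0
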