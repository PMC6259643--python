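# Literature-compiled CXCR2 antagonist potencies, transcribed verbatim by chemical
# series (acylsulfonamides; furyl/heterocyclic diamino-cyclobutenediones;
# N,N'-diphenylureas; nicotinamide N-oxides; triazolethiols; bicyclics).
# ic50 and pic50_printed are the published values as printed, including their
# inconsistencies — see NOTES.md.  Units are as printed per series.
compound_id,series,ic50,ic50_unit,pic50_printed
1,acylsulfonamide,0.07,uM,7.14
2,acylsulfonamide,0.17,uM,6.77
3,acylsulfonamide,0.06,uM,7.19
4,acylsulfonamide,1.30,uM,5.89
5,acylsulfonamide,1.40,uM,5.85
6,acylsulfonamide,0.22,uM,6.66
7,acylsulfonamide,0.26,uM,6.58
8,acylsulfonamide,0.09,uM,7.06
9,acylsulfonamide,0.16,uM,6.80
10,acylsulfonamide,0.02,uM,7.72
11,acylsulfonamide,0.25,uM,6.60
12,acylsulfonamide,0.64,uM,6.19
13,acylsulfonamide,0.12,uM,6.92
14,acylsulfonamide,0.14,uM,6.85
15,acylsulfonamide,0.40,uM,6.40
16,acylsulfonamide,0.52,uM,6.28
17,acylsulfonamide,0.05,uM,7.30
18,acylsulfonamide,0.12,uM,6.92
19,acylsulfonamide,0.07,uM,7.18
20,acylsulfonamide,1.10,uM,5.96
21,acylsulfonamide,1.10,uM,5.96
22,acylsulfonamide,0.88,uM,6.05
23,acylsulfonamide,0.26,uM,6.58
24,acylsulfonamide,0.06,uM,7.24
25,acylsulfonamide,0.02,uM,7.62
26,cyclobutenedione,0.005,nM,8.3
27,cyclobutenedione,0.006,nM,8.24
28,cyclobutenedione,0.004,nM,8.39
29,cyclobutenedione,0.005,nM,8.33
30,cyclobutenedione,0.005,nM,8.32
31,cyclobutenedione,0.017,nM,7.76
32,cyclobutenedione,0.007,nM,8.17
33,cyclobutenedione,0.003,nM,8.55
34,cyclobutenedione,0.094,nM,7.03
35,cyclobutenedione,0.171,nM,6.77
36,cyclobutenedione,0.049,nM,7.31
37,cyclobutenedione,0.15,nM,6.82
38,cyclobutenedione,0.058,nM,7.24
39,cyclobutenedione,0.087,nM,7.06
40,cyclobutenedione,0.0045,nM,8.35
41,cyclobutenedione,0.005,nM,8.30
42,cyclobutenedione,0.009,nM,8.02
43,cyclobutenedione,0.008,nM,8.09
44,cyclobutenedione,0.008,nM,8.12
45,cyclobutenedione,0.003,nM,8.46
46,cyclobutenedione,0.016,nM,7.78
47,cyclobutenedione,8.6,nM,8.06
48,cyclobutenedione,10.9,nM,7.96
49,cyclobutenedione,9.8,nM,8.01
50,cyclobutenedione,9.8,nM,8.01
51,cyclobutenedione,7.5,nM,8.12
52,cyclobutenedione,8.2,nM,8.10
53,cyclobutenedione,8.0,nM,8.10
54,cyclobutenedione,5.8,nM,8.24
55,cyclobutenedione,6.2,nM,8.21
56,cyclobutenedione,6.2,nM,8.21
57,cyclobutenedione,21,nM,7.68
58,cyclobutenedione,50,nM,7.30
59,diphenylurea,906,nM,6.04
60,diphenylurea,63,nM,7.20
61,diphenylurea,10,nM,8.00
62,diphenylurea,114,nM,6.94
63,diphenylurea,7,nM,8.15
64,diphenylurea,12,nM,7.92
65,diphenylurea,25,nM,7.60
66,diphenylurea,6,nM,8.22
67,diphenylurea,22,nM,7.66
68,diphenylurea,57,nM,7.24
69,diphenylurea,22,nM,7.66
70,diphenylurea,320,nM,6.49
71,diphenylurea,860,nM,6.07
72,diphenylurea,10900,nM,4.96
73,diphenylurea,200,nM,6.70
74,diphenylurea,9.3,nM,8.03
75,diphenylurea,39,nM,7.49
76,nicotinamide_n_oxide,130,nM,6.87
77,nicotinamide_n_oxide,400,nM,6.40
78,nicotinamide_n_oxide,460,nM,6.34
79,nicotinamide_n_oxide,90,nM,7.05
80,nicotinamide_n_oxide,32,nM,7.49
81,nicotinamide_n_oxide,280,nM,6.55
82,nicotinamide_n_oxide,1000,nM,6.00
83,triazolethiol,2400,nM,5.62
84,triazolethiol,4400,nM,5.36
85,triazolethiol,7700,nM,5.11
86,triazolethiol,4200,nM,5.38
87,triazolethiol,3500,nM,5.46
88,triazolethiol,3500,nM,5.46
89,triazolethiol,2800,nM,5.55
90,triazolethiol,2300,nM,5.64
91,triazolethiol,2000,nM,5.70
92,triazolethiol,2000,nM,5.70
93,triazolethiol,1400,nM,5.85
94,triazolethiol,1400,nM,5.85
95,triazolethiol,1000,nM,6.00
96,triazolethiol,890,nM,6.05
97,triazolethiol,830,nM,6.08
98,triazolethiol,800,nM,6.10
99,triazolethiol,670,nM,6.17
100,triazolethiol,450,nM,6.35
101,triazolethiol,410,nM,6.39
102,triazolethiol,350,nM,6.46
103,triazolethiol,350,nM,6.46
104,triazolethiol,10000,nM,5.00
105,triazolethiol,4200,nM,5.38
106,triazolethiol,730,nM,6.14
107,triazolethiol,300,nM,6.52
108,triazolethiol,170,nM,6.77
109,triazolethiol,92,nM,7.04
110,triazolethiol,28,nM,7.55
111,bicyclic,160,nM,6.80
112,bicyclic,4,nM,8.40
113,bicyclic,13,nM,7.89
114,bicyclic,630,nM,6.20
115,bicyclic,7,nM,8.15
116,bicyclic,280,nM,6.55
117,bicyclic,140,nM,6.85
118,bicyclic,280,nM,6.55
119,bicyclic,850,nM,6.07
120,bicyclic,5,nM,8.30
121,bicyclic,350,nM,6.46
122,bicyclic,16,nM,7.80
123,bicyclic,2,nM,8.70
124,bicyclic,45,nM,7.35
125,bicyclic,2500,nM,5.60
126,bicyclic,220,nM,6.66
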