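turbine,year,C,T,a,s,s_lwr,s_upr,f,f_lwr,f_upr,p,p_lwr,p_upr
1,2007,1,23,0.92,0.83,0.87,0.99,0.69,0.63,0.76,0.70,0.50,0.85
2,2007,3,45,0.94,0.82,0.64,0.94,0.70,0.63,0.77,0.71,0.48,0.88
3,2007,7,43,1.00,0.89,0.60,0.93,0.74,0.67,0.79,0.85,0.66,0.97
4,2007,1,14,0.52,0.84,0.58,0.93,0.74,0.67,0.80,0.41,0.30,0.49
5,2007,0,51,0.27,0.79,0.60,0.93,0.66,0.63,0.69,0.19,0.13,0.24
6,2007,0,65,0.62,0.59,0.56,0.91,0.65,0.62,0.68,0.30,0.12,0.48
7,2007,1,37,1.00,0.80,0.69,0.96,0.80,0.74,0.84,0.76,0.63,0.88
8,2007,3,37,0.97,0.71,0.60,0.94,0.77,0.70,0.84,0.63,0.34,0.87
9,2007,1,25,0.53,0.82,0.62,0.93,0.74,0.71,0.77,0.41,0.27,0.50
10,2007,0,25,0.66,0.85,0.64,0.94,0.75,0.72,0.79,0.54,0.39,0.63
11,2007,2,54,1.00,0.93,0.55,0.92,0.59,0.51,0.67,0.88,0.71,0.97
12,2007,3,54,1.00,0.75,0.61,0.93,0.63,0.57,0.69,0.65,0.36,0.90
13,2008,0,72,0.91,0.96,0.59,0.93,0.60,0.56,0.64,0.84,0.74,0.90
14,2008,0,83,1.00,0.84,0.50,0.91,0.56,0.51,0.60,0.75,0.52,0.92
15,2008,0,72,0.94,0.82,0.13,0.74,0.68,0.65,0.72,0.71,0.51,0.86
16,2008,1,72,0.83,0.80,0.48,0.90,0.71,0.68,0.74,0.61,0.42,0.76
17,2008,0,27,0.89,0.84,0.53,0.91,0.66,0.61,0.70,0.69,0.51,0.83
18,2008,0,81,1.00,0.85,0.24,0.82,0.56,0.51,0.62,0.76,0.55,0.93
19,2008,5,77,0.95,0.80,0.65,0.89,0.64,0.60,0.67,0.68,0.46,0.86
20,2008,9,78,0.94,0.83,0.36,0.89,0.63,0.60,0.67,0.71,0.52,0.87
21,2008,5,83,0.81,0.82,0.56,0.92,0.64,0.58,0.71,0.60,0.42,0.75
22,2008,3,68,0.82,0.77,0.56,0.92,0.65,0.59,0.71,0.57,0.37,0.74
23,2008,1,12,0.64,0.47,0.54,0.94,0.69,0.65,0.73,0.24,0.09,0.44
24,2008,3,77,0.89,0.75,0.59,0.95,0.65,0.61,0.68,0.59,0.36,0.78
25,2008,0,65,0.46,0.81,0.79,0.98,0.78,0.72,0.84,0.36,0.26,0.43
26,2008,0,83,0.73,0.80,0.42,0.91,0.76,0.71,0.81,0.55,0.40,0.67
27,2008,3,74,0.96,0.72,0.43,0.88,0.63,0.59,0.67,0.60,0.35,0.82
28,2008,1,68,1.00,0.72,0.43,0.88,0.65,0.61,0.68,0.63,0.38,0.85
29,2008,1,80,0.82,0.74,0.45,0.89,0.78,0.73,0.82,0.57,0.35,0.74
30,2008,3,53,0.82,0.73,0.43,0.89,0.74,0.68,0.80,0.55,0.34,0.73
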