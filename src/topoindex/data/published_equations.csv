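eq_no,group,property,index,intercept,slope,r
1,hypouricemic,AlogPs,W,-1.060,0.00599,0.9970
2,hypouricemic,AlogPs,R,-1.057,0.00300,0.9970
3,hypouricemic,AlogPs,A,-0.7926,0.00480,0.9982
4,hypouricemic,AClogP,W,-0.8596,0.00610,0.9971
5,hypouricemic,AClogP,R,-0.8570,0.00305,0.9971
6,hypouricemic,AClogP,A,-0.5875,0.00489,0.9983
7,hypouricemic,XlogP2,Mv,-5.144,0.02257,0.9984
8,hypouricemic,XlogP2,chi0,-3.122,0.39545,0.9976
9,hypouricemic,XlogP2,chi1,-3.384,0.71734,0.9973
10,hypouricemic,XlogP2,B1,5.6126,-8.714,-1.0000
11,hypouricemic,ACD/logP,M,-112.3,1.1217,0.9984
12,hypouricemic,ACD/logP,chi1,-87.95,22.558,0.9972
13,hypouricemic,ACD/logP,chi0v,-56.95,10.794,0.9994
14,hypouricemic,ACD/logP,chi1v,-75.65,26.173,0.9992
15,hypouricemic,ACD/logP,W,-14.00,0.14181,0.9996
16,hypouricemic,ACD/logP,R,-13.94,0.07094,0.9996
17,hypouricemic,ACD/logP,A,-7.640,0.11365,0.9999
18,anti-androgen,AlogPs,chi1,5.6093,-0.4320,-0.8667
19,anti-androgen,AClogP,chi1,5.0751,-0.3574,-0.8910
20,anti-androgen,mlogP,chi1,4.6684,-0.2898,-0.7764
21,anti-androgen,XlogP3,chi1,5.9902,-0.4834,-0.8154
22,anti-androgen,logP_avg,chi1,5.1783,-0.3768,-0.8425
23,anti-androgen,logP_KOWWIN,chi1,6.9299,-0.5693,-0.9099
24,hypouricemic,RP18 (EtOH/H2O),M,-2.520,0.02750,0.9976
25,hypouricemic,RP18 (EtOH/H2O),chi0v,-1.163,0.26467,0.9989
26,hypouricemic,RP18 (EtOH/H2O),chi1v,-1.621,0.64167,0.9985
27,hypouricemic,RP18 (EtOH/H2O),W,-0.1099,0.00348,0.9991
28,hypouricemic,RP18 (EtOH/H2O),R,-0.1085,0.00174,0.9991
29,hypouricemic,RP18 (EtOH/H2O),A,0.04581,0.00279,0.9997
30,hypouricemic,RP18 (ACN/H2O),Mv,-2.358,0.01248,0.9999
31,hypouricemic,RP18 (ACN/H2O),B0,-110.3,42.834,0.9989
32,hypouricemic,RP18 (ACN/H2O),B1,3.5769,-4.798,-0.9974
33,hypouricemic,RP18W (ACN/H2O),W,-0.4364,0.00245,0.9973
34,hypouricemic,RP18W (ACN/H2O),R,-0.4354,0.00122,0.9973
35,hypouricemic,RP18W (ACN/H2O),A,-0.3272,0.00196,0.9984
36,anti-androgen,RP18 (P-2-ol/H2O),B1,4.5928,-7.182,-0.7581
37,anti-androgen,RP18W (P-2-ol/H2O),B0,9.8338,-3.232,-0.8043
38,hypouricemic,M_R,M,-15.89,0.52076,0.9997
39,hypouricemic,M_R,chi0,-0.7278,5.7737,0.9990
40,hypouricemic,M_R,chi1,-4.596,10.479,0.9992
41,hypouricemic,M_R,chi0v,9.8652,5.0076,1.0000
42,hypouricemic,M_R,chi1v,1.1774,12.144,1.0000
43,hypouricemic,M_R,W,29.792,0.06577,1.0000
44,hypouricemic,M_R,R,29.820,0.03290,1.0000
45,hypouricemic,M_R,A,32.753,0.05268,0.9997
46,hypouricemic,P,M,-6.211,0.20575,0.9997
47,hypouricemic,P,chi0,-0.2209,2.2811,0.9989
48,hypouricemic,P,chi1,-1.749,4.1401,0.9991
49,hypouricemic,P,chi0v,3.9624,1.9786,1.0000
50,hypouricemic,P,chi1v,0.53001,4.7984,1.0000
51,hypouricemic,P,W,11.836,0.02599,1.0000
52,hypouricemic,P,R,11.847,0.01300,1.0000
53,hypouricemic,P,A,13.006,0.02082,0.9998
54,hypouricemic,M_V,M,-95.86,1.7703,0.9978
55,hypouricemic,M_V,chi0v,-8.455,17.039,0.9990
56,hypouricemic,M_V,chi1v,-37.97,41.311,0.9987
57,hypouricemic,M_V,W,59.330,0.22386,0.9993
58,hypouricemic,M_V,R,59.426,0.11199,0.9993
59,hypouricemic,M_V,A,69.362,0.17943,0.9998
60,anti-androgen,B_P,M,103.44,1.9858,0.7560
61,anti-androgen,B_P,chi0,-286.5,49.958,0.9324
62,anti-androgen,B_P,chi0v,8.4148,38.328,0.7902
63,anti-androgen,B_P,W,244.79,0.23084,0.8231
64,anti-androgen,B_P,R,245.04,0.11542,0.8230
65,anti-androgen,I_R,chi0v,1.4038,0.01315,0.7992
66,anti-androgen,I_R,chi1v,1.4775,0.01415,0.8622
67,anti-androgen,M_R,chi0,-26.99,6.7763,0.8675
68,anti-androgen,M_R,chi0v,-9.561,7.0284,0.9940
69,anti-androgen,M_R,chi1v,37.344,6.3639,0.9024
70,anti-androgen,M_R,W,40.612,0.03567,0.8724
71,anti-androgen,M_R,R,40.636,0.01784,0.8727
72,anti-androgen,P_SA,Mv,-9.044,0.22389,0.7852
73,anti-androgen,P_SA,chi1,11.136,9.3195,0.9273
74,anti-androgen,P,chi0v,-49.99,7.1096,0.7836
75,anti-androgen,S_T,chi0,-2.977,3.3866,0.7761
76,anti-androgen,S_T,chi1v,29.281,3.1633,0.8029
77,anti-androgen,M_V,M,99.569,0.71158,0.7679
78,anti-androgen,M_V,chi0,-21.71,16.701,0.8834
79,anti-androgen,M_V,chi0v,26.659,16.883,0.9865
80,anti-androgen,M_V,chi1v,143.81,14.571,0.8537
81,anti-androgen,M_V,W,142.43,0.09032,0.9128
82,anti-androgen,M_V,R,142.49,0.04518,0.9131
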