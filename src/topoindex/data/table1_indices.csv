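compound,group,M,Mv,chi0,chi1,chi0v,chi1v,W,R,A,B0,B1
Allopurinol,hypouricemic,96,184,5.9309,3.6481,4.9574,2.7451,76.804,152.786,48.6479,2.5718,0.7468
Oxypurinol,hypouricemic,102,218,6.6903,4.0423,5.3410,2.9328,101.248,201.424,61.1606,2.5845,0.6837
Febuxostat,hypouricemic,190,342,14.499,8.3593,14.6247,6.7450,810.546,1619.431,955.8462,2.6186,0.3456
Abiraterone,anti-androgen,210,246,16.8011,1.5871,16.1181,9.4695,1447.587,2893.781,577.6900,2.4969,0.2531
Bicalutamide,anti-androgen,287,573,19.0629,10.1215,14.7881,7.8966,1749.234,3495.225,661.7294,2.6786,0.2656
Flutamide,anti-androgen,135,399,13.9309,7.5186,10.1154,2.0128,526.913,1051.791,246.1452,2.5929,0.3781
Nilutamide,anti-androgen,160,462,15.1280,7.8722,11.3934,5.9729,1067.496,2132.563,786.2401,2.6346,0.3388
Leflunomide,anti-androgen,166,402,12.5823,7.0160,9.7846,4.3595,588.241,1174.697,274.7566,2.4525,0.3471
Teriflunomide,anti-androgen,170,298,12.8012,6.6709,9.7462,5.0397,640.855,1278.586,297.3176,2.3403,0.3003
Ailanthone,anti-androgen,204,404,17.2760,10.9384,14.4220,9.0418,1152.250,2302.750,456.6286,2.7868,0.3619
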