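rank,h_dist,cell,H,Nad,Nas,Kdrf,Kdrs,KA,CaT,CaL,AHP,M,Rm,Cm,Ibias
326,HS,1,0.5,117,107,215,2.3,2.5,2.5,50,11,0.375,80932,0.5119,-6.79
556,HS,1,0.5,117,220,215,2.3,32,5,50,5.5,0.375,90251,0.4981,-0.93
613,HS,1,0.5,117,107,215,2.3,32,2.5,25,2.75,0.375,89118,0.5282,-1.57
620,HS,1,0.5,117,220,215,2.3,32,5,25,5.5,0.375,90099,0.5025,-0.93
689,HS,1,0.5,117,107,215,2.3,2.5,2.5,25,5.5,0.75,79102,0.5069,-8.19
723,HS,1,0.5,117,60,215,2.3,32,5,25,5.5,0.375,90289,0.4950,-0.846
755,HS,1,0.5,117,60,215,2.3,2.5,5,25,11,0.375,80939,0.5058,-6.83
769,HS,1,0.5,117,107,215,2.3,2.5,1.25,25,5.5,0.75,79183,0.5057,-8.16
26,HS,2,0.5,117,107,215,2.3,2.5,1.25,25,11,0.375,64872,1.046,-15.2
31,HS,2,0.5,117,107,215,2.3,32,5,25,5.5,0.375,68312,1.058,-12.3
39,HS,2,0.5,117,107,215,2.3,2.5,2.5,25,11,0.375,63968,1.060,-15.2
43,HS,2,0.5,117,60,215,2.3,2.5,2.5,25,2.75,0.375,63041,1.042,-16.4
45,HS,2,0.5,117,107,215,2.3,32,5,50,2.75,0.375,66584,1.058,-12.7
60,HS,2,0.5,117,60,215,2.3,32,2.5,12.5,2.75,0.375,67959,1.048,-12.6
67,HS,2,0.5,117,107,215,2.3,32,2.5,50,2.75,0.375,68083,1.047,-12.7
68,HS,2,0.5,117,107,215,2.3,2.5,5,50,11,0.375,64339,1.053,-15.2
225,HSD,1,0.1,230,107,506,42,2.5,1.25,25,5.5,0.75,138328,0.6603,-10.3
356,HSD,1,0.1,230,220,506,42,2.5,2.5,50,2.75,0.375,122359,0.6515,-11.3
913,HSD,1,0.1,230,107,506,42,2.5,1.25,50,5.5,0.75,130845,0.6524,-10.3
1230,HSD,1,0.1,230,60,506,42,2.5,1.25,25,2.75,0.375,131079,0.6574,-11.2
1520,HSD,1,0.1,230,60,506,42,2.5,2.5,12.5,5.5,0.375,130763,0.6520,-10.5
2050,HSD,1,0.1,230,60,506,42,2.5,1.25,25,5.5,0.375,131588,0.6528,-10.5
2173,HSD,1,0.1,230,107,506,42,2.5,2.5,25,5.5,0.375,129748,0.6505,-10.5
2286,HSD,1,0.1,230,220,506,42,2.5,1.25,25,5.5,0.75,130703,0.6547,-10.4
6,HSD,2,0.1,230,60,506,42,2.5,5,25,2.75,0.375,71586,1.086,-7.03
34,HSD,2,0.1,230,107,506,42,2.5,5,25,2.75,0.375,68585,1.083,-7.04
37,HSD,2,0.1,230,107,506,42,2.5,1.25,12.5,2.75,0.75,71079,1.086,-6.94
49,HSD,2,0.1,230,107,506,42,2.5,5,12.5,2.75,0.375,71129,1.083,-7.04
57,HSD,2,0.1,230,107,506,42,2.5,1.25,25,11,0.375,71750,1.082,-5.76
92,HSD,2,0.1,230,60,506,42,2.5,2.5,50,5.5,0.375,71891,1.081,-6.56
96,HSD,2,0.1,230,60,506,42,32,1.25,25,5.5,0.375,72746,1.066,-2.13
109,HSD,2,0.1,230,107,506,42,32,2.5,50,5.5,0.375,75364,1.061,-2.18
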