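Phase,Indication,Time min,Time mid,Time max,Cost min,Cost mid,Cost max,Prob min,Prob mid,Prob max
PC,ABOM,52,66,72,19,21.1,23.2,17.5,35.2,69
PC,ABSSSI,52,66,72,19,21.1,23.2,17.5,35.2,69
PC,CABP,52,66,72,19,21.1,23.2,17.5,35.2,69
PC,CIAI,52,66,72,19,21.1,23.2,17.5,35.2,69
PC,CUTI,52,66,72,19,21.1,23.2,17.5,35.2,69
PC,HABP/VABP,52,66,72,19,21.1,23.2,17.5,35.2,69
P1,ABOM,9,10.5,21.6,7.3,9.7,12,25,33,83.7
P1,ABSSSI,9,10.5,21.6,7.3,9.7,12,25,33,83.7
P1,CABP,9,10.5,21.6,7.3,9.7,12,25,33,83.7
P1,CIAI,9,10.5,21.6,7.3,9.7,12,25,33,83.7
P1,CUTI,9,10.5,21.6,7.3,9.7,12,25,33,83.7
P1,HABP/VABP,9,10.5,21.6,7.3,9.7,12,25,33,83.7
P2,ABOM,12,15,30,7.4,9.2,11,34,50,74
P2,ABSSSI,9,10,30,7.12,8.9,10.68,34,50,74
P2,CABP,12,15,30,7.28,9.1,10.92,34,50,74
P2,CIAI,10,11,30,7.68,9.6,11.52,34,50,74
P2,CUTI,10,11,30,7.28,9.1,10.92,34,50,74
P2,HABP/VABP,16,18,30,12.48,15.6,18.72,34,50,74
P3,ABOM,20,24,47,33.36,41.7,50.04,31.4,67,78.6
P3,ABSSSI,10,12.5,47,26.88,33.6,40.32,31.4,67,78.6
P3,CABP,10,12.5,47,31.04,38.8,46.56,31.4,67,78.6
P3,CIAI,17,21.5,47,40.48,50.6,60.72,31.4,67,78.6
P3,CUTI,17,21.5,47,35.04,43.8,52.56,31.4,67,78.6
P3,HABP/VABP,35,39,47,81.12,101.4,121.68,31.4,67,78.6
P4,ABOM,6,9,12.5,,1.9588,,83,85,99
P4,ABSSSI,6,9,12.5,,1.9588,,83,85,99
P4,CABP,6,9,12.5,,1.9588,,83,85,99
P4,CIAI,6,9,12.5,,1.9588,,83,85,99
P4,CUTI,6,9,12.5,,1.9588,,83,85,99
P4,HABP/VABP,6,9,12.5,,1.9588,,83,85,99
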