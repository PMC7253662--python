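Indication,P1,P2,P3,P4,M1
ABOM,79,323,940,1841,2456
ABSSSI,81,305,884,2432,3066
CABP,92,326,719,2083,2598
CIAI,105,291,863,4008,4494
CUTI,85,295,840,1533,2188
HABP/VABP,98,295,907,2859,3800
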