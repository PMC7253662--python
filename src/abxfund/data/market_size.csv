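Indication,Min,Max
ABOM,2720,
ABSSSI,3070,
CABP,2290,9230
CIAI,2530,
CUTI,5760,
HABP/VABP,1780,
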