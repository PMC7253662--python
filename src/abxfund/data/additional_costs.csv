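Activity,Min,Mid,Max,Spread across
Sample prep.,2.4,2.7,2.9,"P1, P2, P3"
Process dev.,18.7,26.8,34.8,"P1, P2"
Plant design,10.7,13.4,16.1,"P3 (75%), P4 (25%)"
Plant build,69.6,83,96.3,P4
Non-clinical,3.4,3.7,4,"P2, P3, P4"
PAS,8,10,12,"M1, M2, M3"
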