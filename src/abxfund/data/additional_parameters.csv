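Parameter,Min,Mid,Max
Launch success probability (%),40,60,80
Generic entry revenue reduction (%),25,50,75
Generic entry (years),10,12,14
Private discount rate (%),9,11,24
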