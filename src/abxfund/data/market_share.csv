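Years,Min,Max
1,0.05,0.11
2,0.87,1.91
3,1.57,3.47
4,2.57,5.68
5,3.92,8.64
6,5.79,12.77
7,7.52,16.59
8,8.52,18.80
9,10.10,22.30
10:20,12.27,27.08
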