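age,mean_d,lower_d,upper_d
6,1.38,0.38,3.63
7,1.38,0.38,3.63
8,1.25,0.38,3.38
9,0.88,0.13,3.13
10,0.75,-0.13,2.88
11,0.63,-0.38,2.88
12,0.50,-0.38,2.50
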