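age,cr_min_mm,cr_max_mm,cr_mean_mm
6,7.93,8.45,8.19
7,7.09,8.70,7.895
8,7.42,8.41,7.915
9,7.41,8.43,7.92
10,7.41,8.43,7.92
11,7.42,8.41,7.915
12,7.39,8.43,7.91
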