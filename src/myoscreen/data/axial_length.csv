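age,al_min_mm,al_max_mm,al_mean_mm
6,20.93,23.98,22.46
7,21.07,24.04,22.68
8,21.30,24.27,22.90
9,21.45,24.46,23.05
10,21.60,24.67,23.22
11,21.71,24.80,23.38
12,21.79,24.84,23.52
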