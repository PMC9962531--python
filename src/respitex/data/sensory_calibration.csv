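stretch_mm,coefficient_pct,sd_pct,cv
5,27.49,3.13,0.11
10,61.93,10.91,0.18
15,89.89,12.04,0.13
20,136.91,5.72,0.04
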