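setting,rad_per_s,peak_ul_per_s
0.1,0.5,10.4
0.25,1.1,24.6
0.5,1.4,33.5
1.0,1.8,56.0
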