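time_s,q_ul_per_s
0.0,0.0
0.008571,8.0
0.017143,16.0
0.025714,24.0
0.034286,32.0
0.042857,40.0
0.051429,48.0
0.06,56.0
0.071238,52.266667
0.082476,48.533333
0.093714,44.8
0.104952,41.066667
0.11619,37.333333
0.127429,33.6
0.138667,29.866667
0.149905,26.133333
0.161143,22.4
0.172381,18.666667
0.183619,14.933333
0.194857,11.2
0.206095,7.466667
0.217333,3.733333
0.228571,0.0
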