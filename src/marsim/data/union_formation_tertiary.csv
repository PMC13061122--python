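age_years,value
15,0.0
21,0.001
23,0.003
26,0.009
29,0.018
32,0.017
35,0.011
38,0.006
42,0.0035
46,0.002
50,0.0012
55,0.0008
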