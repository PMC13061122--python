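age_years,value
15,0.008
20,0.012
25,0.02
30,0.04
34,0.07
37,0.11
39,0.16
41,0.24
43,0.36
45,0.52
47,0.7
49,0.86
51,0.96
53,0.995
55,1.0
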