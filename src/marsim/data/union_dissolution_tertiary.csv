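age_years,value
15,0.0042
20,0.0038
25,0.0034
30,0.0027
35,0.0022
40,0.0017
45,0.0013
50,0.001
55,0.0009
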