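age_years,value
15,0.0
19,0.002
21,0.005
24,0.013
27,0.019
30,0.016
33,0.011
37,0.006
41,0.0035
45,0.002
49,0.0012
55,0.0008
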