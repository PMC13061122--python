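age_years,value
15,0.0
20,0.002
22,0.004
25,0.011
28,0.019
31,0.016
34,0.011
37,0.006
41,0.0035
45,0.002
49,0.0012
55,0.0008
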