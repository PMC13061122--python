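age_years,value
15,0.0
20,0.002
25,0.01
30,0.03
33,0.055
35,0.075
37,0.095
39,0.11
41,0.12
43,0.12
45,0.06
47,0.02
50,0.0
55,0.0
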