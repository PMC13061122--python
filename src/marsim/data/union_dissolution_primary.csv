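age_years,value
15,0.006
20,0.0054
25,0.0048
30,0.0038
35,0.0031
40,0.0024
45,0.0018
50,0.0014
55,0.0012
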