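age_years,value
15,0.005
20,0.0045
25,0.004
30,0.0032
35,0.0026
40,0.002
45,0.0015
50,0.0012
55,0.001
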