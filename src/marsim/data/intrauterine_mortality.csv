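age_years,value
15,0.18
20,0.13
25,0.11
30,0.12
33,0.14
35,0.17
38,0.23
40,0.3
42,0.38
44,0.47
46,0.55
50,0.7
55,0.85
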