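age_years,value
15,0.55
18,0.9
21,1.0
25,1.0
28,1.0
30,0.96
33,0.86
35,0.75
37,0.63
40,0.4
42,0.26
44,0.14
46,0.07
48,0.03
50,0.01
52,0.0
55,0.0
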