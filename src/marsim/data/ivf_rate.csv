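age_years,value
15,0.26
20,0.28
25,0.29
28,0.285
30,0.27
32,0.25
34,0.23
36,0.2
38,0.16
40,0.11
42,0.06
44,0.025
46,0.012
50,0.004
55,0.001
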