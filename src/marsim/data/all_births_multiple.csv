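age_years,value
15,0.01
20,0.011
25,0.013
30,0.016
33,0.019
36,0.023
38,0.025
40,0.024
43,0.02
46,0.017
50,0.015
55,0.014
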