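age_low,age_high,rate
20,24,5
25,29,10
30,34,25
35,39,80
40,44,180
45,49,260
50,54,250
55,59,230
60,64,245
65,69,255
70,74,240
75,79,215
80,84,175
85,89,120
90,,60
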