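age_low,age_high,rate
15,19,5
20,24,10
25,29,25
30,34,80
35,39,180
40,44,260
45,49,250
50,54,230
55,59,245
60,64,255
65,69,240
70,74,215
75,79,175
80,84,120
85,,60
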