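age_low,age_high,rate
15,19,5
20,24,10
25,29,25
30,34,98
35,39,269
40,44,337
45,49,360
50,54,358
55,59,343
60,64,319
65,69,288
70,74,250
75,79,206
80,84,158
85,,111
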