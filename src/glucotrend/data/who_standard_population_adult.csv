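age_lo,age_hi,weight
18,20,3.388
20,25,8.22
25,30,7.93
30,35,7.61
35,40,7.15
40,45,6.59
45,50,6.04
50,55,5.37
55,60,4.55
60,65,3.72
65,70,2.96
70,75,2.21
75,80,1.52
80,200,1.54
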