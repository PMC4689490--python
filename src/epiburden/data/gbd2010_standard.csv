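age,ex
0,86.02
1,85.21
5,81.25
10,76.27
15,71.29
20,66.35
25,61.40
30,56.46
35,51.53
40,46.64
45,41.80
50,37.05
55,32.38
60,27.81
65,23.29
70,18.93
75,14.80
80,10.99
85,7.64
90,5.05
95,3.31
100,2.23
105,1.63
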