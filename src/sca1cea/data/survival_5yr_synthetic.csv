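sara,survival_5yr
14.000000,0.980000
15.000000,0.934619
16.000000,0.889616
17.000000,0.845003
18.000000,0.800793
19.000000,0.757001
20.000000,0.713643
21.000000,0.670736
22.000000,0.628298
23.000000,0.586349
24.000000,0.544914
25.000000,0.504016
26.000000,0.463684
27.000000,0.423950
28.000000,0.384849
29.000000,0.346424
30.000000,0.308723
31.000000,0.271803
32.000000,0.235731
33.000000,0.200590
34.000000,0.166486
35.000000,0.133554
36.000000,0.101977
37.000000,0.072022
38.000000,0.044116
39.000000,0.019084
40.000000,0.000000
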