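id,rest_br,rest_alpha,iq_br,iq_alpha,iq_score
1,19.40,0.77,20.50,0.55,4
2,21.80,0.80,27.40,0.69,5
3,9.20,0.94,4.20,0.16,4
5,23.80,0.50,11.90,0.65,2
6,11.20,0.79,16.80,0.80,2
7,14.80,1.29,9.10,0.69,7
9,12.80,0.61,9.80,0.64,2
10,14.40,0.54,16.50,0.64,4
11,29.80,0.85,41.80,0.58,2
12,11.20,0.73,7.00,0.70,3
13,12.80,1.21,24.10,0.74,6
14,17.40,1.26,34.10,0.60,5
15,10.60,0.59,10.60,0.23,3
16,52.20,0.57,36.70,0.67,3
17,38.60,0.90,16.90,0.59,2
18,10.80,0.89,13.80,0.82,2
19,8.80,0.43,10.20,0.78,4
20,15.00,0.64,12.90,0.52,5
21,19.20,1.01,45.40,0.78,4
22,15.60,0.63,12.50,0.53,6
23,31.00,0.85,18.40,0.61,6
25,10.60,0.88,11.40,0.81,8
26,16.00,0.89,21.70,0.60,6
27,11.40,0.64,25.60,0.62,3
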