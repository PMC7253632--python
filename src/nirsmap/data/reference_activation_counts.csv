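subject,n_back_1,n_back_2,n_back_3,stroop_1,stroop_2,stroop_3,vft_1,vft_2,vft_3
1,17,23,29,31,33,36,39,27,37
2,32,26,19,23,19,15,28,32,32
3,36,33,39,32,34,35,19,32,31
4,23,31,18,12,12,18,6,23,20
5,10,37,32,20,9,8,11,16,18
6,21,22,16,12,25,22,27,34,24
7,16,30,21,13,38,23,40,37,27
8,15,15,25,9,17,16,19,31,29
9,27,27,20,21,33,22,18,11,17
10,35,10,30,38,7,24,40,41,24
11,40,36,35,39,33,38,28,35,39
12,31,28,28,19,30,21,11,22,8
13,44,31,35,37,35,24,3,22,34
14,26,22,28,38,10,6,28,22,31
15,35,1,30,36,25,13,3,17,30
16,23,8,11,19,30,21,25,17,25
17,8,16,9,20,14,15,22,29,27
18,47,26,41,8,17,20,42,39,40
19,28,40,27,41,15,14,21,19,15
20,23,14,1,31,30,30,1,27,46
21,16,28,38,20,3,3,33,28,28
22,40,2,2,6,10,12,10,30,31
23,30,43,21,13,30,18,20,24,31
24,21,31,47,36,48,24,36,35,43
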