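item_id,set_label,immediate_amount,delayed_amount,delay_days,k_nominal
1,medium,54,55,117,0.00016
2,large,55,75,61,0.006
3,small,19,25,53,0.006
4,large,31,85,7,0.25
5,small,14,25,19,0.041
6,medium,47,50,160,0.0004
7,small,15,35,13,0.1
8,medium,25,60,14,0.1
9,large,78,80,162,0.00016
10,medium,40,55,62,0.006
11,small,11,30,7,0.25
12,large,67,75,119,0.001
13,small,34,35,186,0.00016
14,medium,27,50,21,0.041
15,large,69,85,91,0.0025
16,medium,49,60,89,0.0025
17,large,80,85,157,0.0004
18,small,24,35,29,0.016
19,large,33,80,14,0.1
20,small,28,30,179,0.0004
21,medium,34,50,30,0.016
22,small,25,30,80,0.0025
23,large,41,75,20,0.041
24,medium,54,60,111,0.001
25,large,54,80,30,0.016
26,small,22,25,136,0.001
27,medium,20,55,7,0.25
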