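item_id,set_label,immediate_amount,delayed_amount,delay_days,k_nominal
1,small,34,35,43,0.0007
2,medium,34,50,5,0.094
3,large,83,85,35,0.0007
4,small,19,25,9,0.035
5,medium,52,55,30,0.0019
6,large,31,85,7,0.25
7,small,25,30,15,0.013
8,medium,58,60,49,0.0007
9,large,62,80,8,0.035
10,small,11,30,7,0.25
11,medium,50,55,20,0.005
12,large,79,85,40,0.0019
13,small,22,25,27,0.005
14,medium,44,55,7,0.035
15,large,69,80,12,0.013
16,small,24,35,5,0.094
17,medium,49,60,17,0.013
18,large,57,85,5,0.094
19,small,28,30,38,0.0019
20,medium,20,55,7,0.25
21,large,71,75,11,0.005
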