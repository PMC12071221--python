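hour_slot,rate
0,0.3534
1,0.3370
2,0.3233
3,0.2301
4,0.2767
5,0.2356
6,0.3452
7,0.4740
8,0.6548
9,0.7562
10,0.8877
11,0.8301
12,0.7616
13,0.7397
14,0.7178
15,0.6110
16,0.7699
17,0.7178
18,0.6247
19,0.6575
20,0.5945
21,0.5534
22,0.4466
23,0.4685
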