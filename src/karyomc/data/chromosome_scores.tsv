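chromosome	score	mu
1	-0.143640496	0.999943914
2	0.638322635	1.000249277
3	0.597508197	1.000233336
4	0.106407616	1.000041550
5	-0.785208831	0.999693447
6	-0.664148445	0.999740704
7	3.039521587	1.001187547
8	1.650903175	1.000644836
9	0.765873656	1.000299095
10	-1.23443224	0.999518107
11	0.210103365	1.000082042
12	1.720482377	1.000672022
13	-1.207617162	0.999528573
14	-0.712581034	0.999721797
15	-0.751608856	0.999706562
16	-1.277797927	0.999501183
17	-0.784673321	0.999693656
18	-1.428496154	0.999442371
19	0.809097907	1.000315978
20	1.780741874	1.000695568
21	1.568732394	1.000612731
22	-1.576297101	0.999384693
23	0	1
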