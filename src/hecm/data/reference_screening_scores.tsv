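peak	vip	miv
1	0.781	-0.256
2	0.966	-0.254
3	0.861	0.185
4	0.767	0.150
5	0.830	0.200
6	0.783	-0.070
7	0.900	-0.190
8	0.851	0.001
9	1.025	0.255
10	1.798	0.342
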