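rank	hub	degree	bottleneck	betweenness
1	TP53	1817	TP53	0.198765
2	AKT1	1623	CTNNB1	0.11618
3	CTNNB1	1426	AKT1	0.11499
4	EGFR	1276	EGFR	0.096395
5	HRAS	980	CYCS	0.072343
6	JUN	966	RHOA	0.063284
7	MAPK3	908	JUN	0.054568
8	RHOA	838	HRAS	0.0481
9	EGF	814	EGF	0.047273
10	KRAS	801	FOS	0.041709
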