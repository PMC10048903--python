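bnh	SN-1	SN-2	SN-3	SN-4	SN-5
HRAS	30	85	92	5	4
TP53	30	83	72	14	3
EGFR	29	80	77	7	5
JUN	30	83	70	10	3
AKT1	27	78	70	12	5
CTNNB1	27	77	73	6	3
EGF	29	75	59	1	4
RHOA	30	68	63	1	5
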