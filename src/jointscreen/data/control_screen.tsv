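gene_id	ligation_pct	plasmid_pct	published_ratio
g10	0.86	0.13	0.15
g22	3.10	0.07	0.02
g38	14.84	26.83	1.81
g119	11.70	19.53	1.67
g121	2.79	15.74	5.63
g137	0.48	13.16	27.2
g150	21.38	3.81	0.18
g178	21.74	10.58	0.49
g246	23.11	10.17	0.44
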