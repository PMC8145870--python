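gene_id	ligation_pct	plasmid_pct	published_ratio	published_sd
g01	1.31	3.52	2.69	0.114
g03	1.26	5.33	4.22	0.546
g04	0.89	2.93	3.30	0.167
g05	3.36	0.01	0.003	0.001
g06	1.46	3.56	2.43	0.328
g08	1.28	3.85	3.01	0.196
g09	2.80	4.30	1.53	0.027
g10	1.08	1.63	1.50	0.334
g11	1.07	2.97	2.78	0.043
g13	2.87	5.71	1.99	0.202
g15	8.64	5.21	0.60	0.074
g17	7.79	5.49	0.71	0.014
g18	36.90	41.23	1.12	0.017
g23	12.09	3.28	0.27	0.005
g26	19.23	12.80	0.67	0.055
g40	11.47	3.63	0.32	0.036
g48	3.40	15.39	4.52	0.288
g50	2.67	4.08	1.53	0.099
g51	0.91	5.41	5.96	0.072
g52	6.75	3.81	0.56	0.033
g58	0.96	0.33	0.34	0.056
g59	2.36	17.27	7.32	1.827
g61	2.71	9.41	3.47	0.047
g64	7.91	2.07	0.26	0.024
g65	5.39	5.40	1.00	0.049
g68	1.31	1.06	0.81	0.034
g69	8.18	5.62	0.69	0.023
g71	11.59	10.57	0.91	0.059
g72	4.08	2.43	0.59	0.064
g73	10.71	2.34	0.22	0.019
g76	3.94	4.60	1.17	0.068
g77	11.44	4.77	0.42	0.051
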