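gene_id	fraction	fraction_sd
g01	0.680	0.166
g03	1.003	0.015
g04	0.672	0.035
g05	0.164	0.003
g06	0.684	0.193
g08	0.658	0.130
g09	0.827	0.145
g10	0.463	0.186
g11	0.901	0.250
g13	1.179	0.428
g15	1.104	0.349
g17	0.868	0.224
g23	0.683	0.200
g48	1.711	0.106
g50	0.746	0.234
g51	0.440	0.180
g52	0.332	0.089
g64	0.332	0.089
g65	0.515	0.140
g68	0.451	0.077
g69	0.795	0.237
g76	1.296	0.505
g77	0.974	0.481
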