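seq_id	size	shared_p28	pct_p28	shared_azurin	pct_azurin	polar_pct_ligand	nonpolar_pct_ligand	polar_pct_receptor	nonpolar_pct_receptor
p1seq09	35	16	53.33	7	28.00	50.00	50.00	60.00	40.00
p1seq16	212	16	53.33	20	80.00	60.70	39.30	62.75	37.25
p2seq05	262	17	56.67	22	88.00	52.24	47.76	55.00	45.00
p2seq08	71	10	33.33	16	64.00	52.17	47.83	61.29	38.71
p2seq14	35	0	0.00	0	0.00	52.38	47.62	64.29	35.71
p2seq18	84	0	0.00	0	0.00	55.56	44.44	63.64	36.36
p2seq20	41	8	26.67	20	80.00	50.00	50.00	64.52	35.48
p2seq32	354	0	0.00	0	0.00	57.50	42.50	51.85	48.15
p2seq33	357	0	0.00	4	16.00	58.33	41.67	55.17	44.83
p3seq02	31	16	53.33	8	32.00	47.37	52.63	57.69	42.31
p3seq04	31	0	0.00	0	0.00	55.56	44.44	64.29	35.71
p3seq16	53	0	0.00	0	0.00	45.00	55.00	54.55	45.45
p3seq17	69	11	36.67	23	92.00	54.17	45.83	59.38	40.62
p3seq24	77	14	46.67	7	28.00	42.86	57.14	59.09	40.91
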