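variant_id	SIFT	CADD	REVEL	MutationAssessor	PolyPhen2
rs1023630775	0.01	22.1	0.62	1.2	0.44
rs1354960600	0.03	18.4	0.41	2.3	0.71
c.869G>A	0.00	28.3	0.88	3.4	0.998
c.929T>C	0.02	25.1	0.76	2.8	0.95
c.973C>T	0.01	33.0	0.81	3.1	0.99
c.1018G>A	0.04	23.6	0.69	2.1	0.62
c.1064T>G	0.00	27.2	0.91	3.7	1.0
c.1169C>T	0.12	24.8	0.66	2.5	0.93
c.1214C>A	0.03	21.9	0.58	2.0	0.89
c.1259C>T	0.01	29.4	0.84	3.2	0.97
c.1304A>G	0.02	26.7	0.73	1.6	0.91
c.1342T>C	0.00	31.5	0.93	3.9	1.0
c.134T>C	0.04	19.7	0.55	2.2	0.86
c.358T>C	0.01	24.2	0.64	2.6	0.48
c.524G>T	0.02	22.8	0.52	1.9	0.88
c.1618C>G	0.05	20.3	0.57	2.4	0.90
c.34G>A	0.61	3.2	0.08	0.4	0.02
c.199G>A	0.33	8.1	0.12	0.7	0.10
c.263G>A	0.15	12.4	0.21	0.9	0.23
c.392C>T	0.04	15.2	0.31	1.1	0.55
c.449A>G	0.27	6.9	0.14	.	0.08
c.690A>C	0.44	11.0	0.18	0.6	0.12
c.740A>G	0.52	7.4	0.10	0.3	0.05
c.804G>C	0.09	14.6	0.44	1.4	0.81
c.997A>G	0.72	2.8	0.05	0.2	.
c.1077C>A	0.38	9.6	0.16	0.8	0.19
c.1192G>A	0.02	16.8	0.49	2.0	0.60
c.1399A>G	0.21	10.5	0.26	1.0	0.35
c.1465A>T	0.88	1.9	0.04	0.1	0.00
c.1573C>T	0.13	13.3	0.37	1.7	0.66
c.1627G>A	0.01	25.0	.	.	.
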