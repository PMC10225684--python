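variant_id	AC	AN	AF	source_db	subset
c.839G>A	.	.	5.19e-05	gnomAD	reported_snp
c.805C>A	17	500000	3.4e-05	gnomAD	reported_snp
c.478T>C	.	250000	3.06e-05	gnomAD	reported_snp
c.478T>C	4	121412	.	ExAC	reported_snp
c.558T>A	.	.	3e-05	gnomAD	reported_snp
c.649T>A	.	.	2.95e-05	ExAC	reported_snp
c.566T>G	.	.	2.85e-05	gnomAD	reported_snp
c.778G>A	11	400000	2.75e-05	gnomAD	reported_snp
c.784C>T	.	.	2.65e-05	ExAC	reported_snp
c.835C>T	.	.	2.55e-05	gnomAD	reported_snp
c.877G>T	.	.	2.45e-05	gnomAD	reported_snp
c.898C>T	.	.	2.35e-05	ExAC	reported_snp
c.920G>A	9	400000	2.25e-05	gnomAD	reported_snp
c.931A>G	.	.	2.15e-05	gnomAD	reported_snp
c.953T>C	.	.	2.05e-05	ExAC	reported_snp
c.1108G>A	.	.	1.95e-05	gnomAD	reported_snp
c.1127G>A	.	.	1.85e-05	gnomAD	reported_snp
c.1133T>C	7	400000	1.75e-05	gnomAD	reported_snp
c.1247C>A	.	.	1.55e-05	ExAC	reported_snp
c.1273A>C	.	.	6.7e-06	gnomAD	reported_snp
c.1282G>T	.	.	6.7e-06	gnomAD	reported_snp
c.223-14_223-2del13	35	140000	0.00025	gnomAD	recurrent_deletion
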