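variant_id	AC	AN	AF	source_db	subset
rs1023630775	.	.	8e-05	gnomAD	database_missense
rs1354960600	.	.	7.2e-05	gnomAD	database_missense
c.869G>A	.	.	6.5e-05	gnomAD	database_missense
c.929T>C	.	.	6e-05	ExAC	database_missense
c.973C>T	.	.	5.5e-05	gnomAD	database_missense
c.1018G>A	.	.	5e-05	gnomAD	database_missense
c.1064T>G	.	.	4.5e-05	ExAC	database_missense
c.1169C>T	.	.	4e-05	gnomAD	database_missense
c.1214C>A	.	.	3.6e-05	gnomAD	database_missense
c.1259C>T	.	.	3.2e-05	gnomAD	database_missense
c.1304A>G	.	.	2.8e-05	ExAC	database_missense
c.1342T>C	.	.	2.4e-05	gnomAD	database_missense
c.134T>C	.	.	2e-05	gnomAD	database_missense
c.358T>C	.	.	1.6e-05	gnomAD	database_missense
c.524G>T	.	.	1.4e-05	ExAC	database_missense
c.1618C>G	.	.	1.16e-05	gnomAD	database_missense
c.34G>A	.	.	5e-06	gnomAD	database_missense
c.199G>A	.	.	4e-06	gnomAD	database_missense
c.263G>A	.	.	6e-06	gnomAD	database_missense
c.392C>T	.	.	3e-06	ExAC	database_missense
c.449A>G	.	.	5e-06	gnomAD	database_missense
c.690A>C	.	.	7e-06	gnomAD	database_missense
c.740A>G	.	.	2e-06	gnomAD	database_missense
c.804G>C	.	.	4e-06	ExAC	database_missense
c.997A>G	.	.	8e-06	gnomAD	database_missense
c.1077C>A	.	.	6e-06	gnomAD	database_missense
c.1192G>A	.	.	3e-06	gnomAD	database_missense
c.1399A>G	.	.	5e-06	ExAC	database_missense
c.1465A>T	.	.	2e-06	gnomAD	database_missense
c.1573C>T	.	.	4e-06	gnomAD	database_missense
c.1627G>A	.	.	2e-06	gnomAD	database_missense
rs760151963	.	.	9e-06	gnomAD	database_nonsense
rs1281934664	.	.	8e-06	gnomAD	database_nonsense
rs763592153	.	.	7e-06	ExAC	database_nonsense
rs1457057185	.	.	6e-06	gnomAD	database_nonsense
rs1176737926	.	.	4.6e-06	gnomAD	database_nonsense
rs751701388	.	.	3.5e-06	gnomAD	database_nonsense
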