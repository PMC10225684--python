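variant_id	cdna	protein	consequence	zygosity	patient_id	source
c.478T>C	c.T478C	p.S160P	.	homozygous	P01	reported_clinical
c.478T>C	c.T478C	p.S160P	.	homozygous	P02	reported_clinical
c.478T>C	c.T478C	p.Ser160Pro	.	homozygous	P03	reported_clinical
c.478T>C	c.T478C	p.S160P	.	homozygous	P04	reported_clinical
c.478T>C	c.T478C	p.S160P	.	homozygous	P05	reported_clinical
c.478T>C	c.T478C	p.S160P	.	homozygous	P06	reported_clinical
c.478T>C	c.T478C	p.S160P	.	homozygous	P07	reported_clinical
c.558T>A	c.T558A	p.Y186*	missense	homozygous	P08	reported_clinical
c.784C>T	c.C784T	p.R262*	missense	homozygous	P09	reported_clinical
c.877G>T	c.G877T	p.D293Y	.	homozygous	P10	reported_clinical
c.1108G>A	c.G1108A	p.G370R	.	homozygous	P11	reported_clinical
c.1127G>A	c.G1127A	p.R376Q	.	homozygous	P12	reported_clinical
c.1376C>A	c.C1376A	p.A459E	.	homozygous	P13	reported_clinical
c.1528C>A	c.C1528A	p.P510T	.	homozygous	P14	reported_clinical
c.1225-2A>G	c.A1225-2G	.	.	homozygous	P15	reported_clinical
c.877-1G>A	c.G877-1A	.	.	homozygous	P16	reported_clinical
c.649T>A	c.T649A	p.Y217N	.	heterozygous	P17	reported_clinical
c.1282G>T	c.G1282T	p.E428*	.	heterozygous	P18	reported_clinical
c.223-14_223-2del13	c.223-14_223-2del13	.	.	compound_het_partner	P19	reported_clinical
c.716delA	c.716delA	.	.	compound_het_partner	P19	reported_clinical
c.223-14_223-2del13	c.223-14_223-2del13	.	.	compound_het_partner	P20	reported_clinical
c.898C>T	c.C898T	p.Q300*	.	compound_het_partner	P20	reported_clinical
c.223-14_223-2del13	c.223-14_223-2del13	.	.	compound_het_partner	P21	reported_clinical
c.1247C>A	c.C1247A	p.P416H	.	compound_het_partner	P21	reported_clinical
c.223-14_223-2del13	c.223-14_223-2del13	.	.	compound_het_partner	P22	reported_clinical
c.1273A>C	c.A1273C	p.T425P	.	compound_het_partner	P22	reported_clinical
c.223-14_223-2del13	c.223-14_223-2del13	.	.	compound_het_partner	P23	reported_clinical
c.1300C>T	c.C1300T	p.Q434*	.	compound_het_partner	P23	reported_clinical
c.223-14_223-2del13	c.223-14_223-2del13	.	.	compound_het_partner	P24	reported_clinical
c.1330_1335del	c.1330_1335del6	.	.	compound_het_partner	P24	reported_clinical
c.223-14_223-2del13	c.223-14_223-2del13	.	.	compound_het_partner	P25	reported_clinical
c.1345A>G	c.A1345G	p.T449A	.	compound_het_partner	P25	reported_clinical
p.P160*	.	p.P160*	.	compound_het_partner	P26	reported_clinical
c.566T>G	c.T566G	p.L189R	.	compound_het_partner	P26	reported_clinical
c.778G>A	c.G778A	p.A260T	.	compound_het_partner	P27	reported_clinical
c.835C>T	c.C835T	p.R279C	.	compound_het_partner	P27	reported_clinical
c.839G>A	c.G839A	p.R280Q	.	compound_het_partner	P28	reported_clinical
c.920G>A	c.G920A	p.R307Q	.	compound_het_partner	P28	reported_clinical
c.931A>G	c.A931G	p.I311V	.	compound_het_partner	P29	reported_clinical
c.953T>C	c.T953C	p.Ile318Thr	.	compound_het_partner	P29	reported_clinical
c.1133T>C	c.T1133C	p.L378P	.	compound_het_partner	P30	reported_clinical
c.1224+2T>C	c.T1224+2C	.	.	compound_het_partner	P30	reported_clinical
c.1369G>T	c.G1369T	p.G457*	.	compound_het_partner	P31	reported_clinical
c.1108G>A	c.G1108A	p.G370R	.	compound_het_partner	P31	reported_clinical
c.1282G>T	c.G1282T	p.E428*	.	compound_het_partner	P32	reported_clinical
c.778G>A	c.G778A	p.A260T	.	compound_het_partner	P32	reported_clinical
c.1247C>A	c.C1247A	p.P416H	.	compound_het_partner	P33	reported_clinical
c.1376C>A	c.C1376A	p.A459E	.	compound_het_partner	P33	reported_clinical
c.1273A>C	c.A1273C	p.T425P	.	compound_het_partner	P34	reported_clinical
c.898C>T	c.C898T	p.Q300*	.	compound_het_partner	P34	reported_clinical
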