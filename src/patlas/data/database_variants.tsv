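variant_id	cdna	protein	consequence	zygosity	patient_id	source
rs1023630775	c.T608A	p.M203K	.	.	.	database_predicted
rs1354960600	c.A622C	p.T208P	.	.	.	database_predicted
c.869G>A	c.G869A	p.G290E	.	.	.	database_predicted
c.929T>C	c.T929C	p.L310P	.	.	.	database_predicted
c.973C>T	c.C973T	p.R325W	.	.	.	database_predicted
c.1018G>A	c.G1018A	p.G340R	.	.	.	database_predicted
c.1064T>G	c.T1064G	p.L355R	.	.	.	database_predicted
c.1169C>T	c.C1169T	p.S390F	.	.	.	database_predicted
c.1214C>A	c.C1214A	p.A405D	.	.	.	database_predicted
c.1259C>T	c.C1259T	p.P420L	.	.	.	database_predicted
c.1304A>G	c.A1304G	p.Y435C	.	.	.	database_predicted
c.1342T>C	c.T1342C	p.W448R	.	.	.	database_predicted
c.134T>C	c.T134C	p.L45P	.	.	.	database_predicted
c.358T>C	c.T358C	p.C120R	.	.	.	database_predicted
c.524G>T	c.G524T	p.G175V	.	.	.	database_predicted
c.1618C>G	c.C1618G	p.R540G	.	.	.	database_predicted
c.34G>A	c.G34A	p.V12I	.	.	.	database_predicted
c.199G>A	c.G199A	p.A67T	.	.	.	database_predicted
c.263G>A	c.G263A	p.S88N	.	.	.	database_predicted
c.392C>T	c.C392T	p.T131M	.	.	.	database_predicted
c.449A>G	c.A449G	p.N150S	.	.	.	database_predicted
c.690A>C	c.A690C	p.E230D	.	.	.	database_predicted
c.740A>G	c.A740G	p.K247R	.	.	.	database_predicted
c.804G>C	c.G804C	p.Q268H	.	.	.	database_predicted
c.997A>G	c.A997G	p.I333V	.	.	.	database_predicted
c.1077C>A	c.C1077A	p.D359E	.	.	.	database_predicted
c.1192G>A	c.G1192A	p.V398I	.	.	.	database_predicted
c.1399A>G	c.A1399G	p.S467G	.	.	.	database_predicted
c.1465A>T	c.A1465T	p.T489S	.	.	.	database_predicted
c.1573C>T	c.C1573T	p.P525S	.	.	.	database_predicted
c.1627G>A	c.G1627A	p.V543M	.	.	.	database_predicted
rs760151963	c.T485A	p.L162*	.	.	.	database_nonsense
rs1281934664	c.C541T	p.Q181*	.	.	.	database_nonsense
rs763592153	c.C709T	p.R237*	.	.	.	database_nonsense
rs1457057185	c.T944G	p.L315*	.	.	.	database_nonsense
rs1176737926	c.C1030T	p.Q344*	.	.	.	database_nonsense
rs751701388	c.C1087T	p.Q363*	.	.	.	database_nonsense
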