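##fileformat=VCFv4.2
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele number">
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=DB,Number=1,Type=String,Description="Source database">
##contig=<ID=15>
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO
15	44669205	c.805C>A	C	A	.	PASS	AC=17;AN=500000;AF=3.4e-05;DB=gnomAD
15	44669310	c.778G>A	G	A	.	PASS	AC=11;AN=400000;AF=2.75e-05;DB=gnomAD
15	44669388	c.920G>A	G	A	.	PASS	AC=9;AN=400000;AF=2.25e-05;DB=gnomAD
15	44669412	c.1133T>C	T	C	.	PASS	AC=7;AN=400000;AF=1.75e-05;DB=gnomAD
15	44669977	c.478T>C	T	C	.	PASS	AN=250000;AF=3.06e-05;DB=gnomAD
15	44670011	c.839G>A	G	A	.	PASS	AF=5.19e-05;DB=gnomAD
15	44670102	c.558T>A	T	A	.	PASS	AF=3e-05;DB=gnomAD
15	44670241	c.649T>A	T	A	.	PASS	AF=2.95e-05;DB=ExAC
15	44670388	c.1273A>C	A	C	.	PASS	AF=6.7e-06;DB=gnomAD
15	44670456	c.1282G>T	G	T	.	PASS	AF=6.7e-06;DB=gnomAD
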