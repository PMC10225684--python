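# Methods

## Scope and model

`patlas` re-analyses the mutation spectrum of *PATL2* (PAT1 homologue 2,
OOMD4), a translational repressor required for human oocyte maturation.
Biallelic loss-of-function causes oocytes to arrest at the germinal-vesicle
(GV) or metaphase-I (MI) stage, fail to extrude the first polar body (PB1),
or present as empty/atretic follicles. The package operates entirely on
curated tables — a clinical mutation lineage, population allele-frequency
extracts, per-tool predictor scores and a pooled patient cohort — and never
queries live databases or computes structural predictions; conservation and
predictor scores are consumed as inputs.

## Coordinate system and gene model

All intervals are 1-based and inclusive at both ends. The merged coding
sequence is 1632 nt (543 residues + stop), with exons 1–2 taken from one
RefSeq transcript and 3–16 from another, as the clinical literature does.
The residue encoded by coding base *n* is ⌈*n*/3⌉. Domain intervals:
PAT1 (the mRNA-decay-factor RNA-binding domain) p.252–491, FUGUE
(CATH-based) p.158–534, N-terminal p.1–239, C-terminal p.492–543; nested
intervals are allowed, so a PAT1 residue is also a FUGUE residue. Conserved
intervals are p.201–285 and p.451–530.

Helix bounds (H1–H23) are a curated, editable table: only two helices
(H9 p.252–263, H10 p.269–277) have published coordinates, and secondary-
structure predictors disagree on the rest. The bundled table is calibrated
so the lineage-level helical tally (21/31) holds; it carries no claim of
crystallographic precision, which is why helical fractions and the
16-SNP consensus count are treated as regression checks against the
bundled fixtures rather than independent reproductions.

Intronic variants are anchored to their nearest coding base: an acceptor
change such as c.1225-2A>G maps to residue 409 (the first residue of the
exon it serves) for domain membership, but keeps exon label "intronic" and
no helix label. A fully intronic deletion (c.223-14_223-2del13) is a
deletion, not a splice-site substitution, matching how the source lineage
tallies its 18/7/3/3 consequence classes.

## HGVS dialect

The clinical literature writes substitutions ref-first (`c.T478C`,
`c.A1225-2G`); the parser accepts both this dialect and standard HGVS
(`c.478T>C`, `c.1225-2A>G`) and normalizes to the standard form. Parsed
values compare equal across dialects; rendering then reparsing is the
identity. Consequence priority is nonsense > splice > deletion > missense:
an annotated stop codon wins regardless of other notation; substitutions
within 20 bases of a junction are splice candidates (the largest offset in
the curated data is −14); deletions without a stated protein product stay
"deletion" rather than "frameshift". Protein-only records (e.g. p.P160*,
whose cDNA is unrecoverable — no single-nucleotide change converts a
proline codon to a stop) are allowed.

## Pathogenicity consensus

Five scored tools (SIFT ≤ 0.05, CADD ≥ 10, REVEL ≥ 0.5, MutationAssessor
≥ 1.9, PolyPhen-2 ≥ 0.85) plus a conservation vote (residue inside a
conserved interval) each cast pathogenic/benign votes; ≥ 4 distinct tools
voting pathogenic labels a variant *predicted pathogenic*. Only the CADD
cutoff is fixed by the curated analysis; the others follow each tool's
published damaging convention and live in `thresholds.yaml`, overridable.
Whether conservation counts as a "program" is genuinely open in the source;
we include it in the roster (config-exposed), which is what lets the two
conserved-region SNPs (p.M203K, p.T208P) reach four votes. Nonsense
variants bypass voting (`auto_pathogenic`) and are tallied separately.
Variants scored by fewer than four tools are `not_labelled` with an
insufficient-evidence flag. The rule counts distinct tools, unweighted;
adding a pathogenic vote can never demote a variant.

## Frequency aggregation and carrier estimates

Cumulative allele frequency is the sum of per-site frequencies over unique
sites. Duplicate sites across databases (gnomAD/ExAC) are resolved to the
source with the larger allele number — the source literature pools the two
without stating a rule, so the larger denominator is our default and is
configurable. Carrier frequency offers two models: the source convention
(carrier = cumulative allele frequency, which reproduces the printed
figures) and Hardy–Weinberg (2p(1−p)), selectable via `--carrier-model`.
"1 in N" figures are reciprocals rounded to three significant figures;
plain integer rounding would print 1/2079 where the literature prints
1/2080. The printed per-site "top three" values (0.00519 …) are stored on
the 10⁻⁵ scale, the only reading consistent with the printed cumulative
48.09 per 100,000. The component sum 48.09 + 64.86 + 3.81 per 100,000
(≈ 1.17‰, 1/856) does not equal the published headline 1.14‰ (1/877); the
report prints the computed sum and logs the discrepancy rather than
reconciling it.

## Amino-acid chemistry

Residues are partitioned into four side-chain categories (nonpolar;
polar uncharged; polar, positive; polar, negative) from a config table
that defaults to standard chemistry. Cross-category substitutions are
flagged as destabilising candidates, with extra flags for proline gain
(rigid imino ring), glycine loss (loss of backbone freedom), charge gain
or loss, and hydrophobic-to-polar changes. Two lineage substitutions are
described in the source prose with categories that contradict standard
chemistry (p.G370R called "polar uncharged → polar negative", p.D293Y
called "polar positive → polar uncharged"); the pipeline computes the
standard-chemistry labels and records both versions in the discrepancy
log without guessing intent.

## Phenotype pooling

Stage percentages are 100·count/total at two decimals; they are exactly
recomputable from the counts. Oocytes-per-cycle is a ratio of totals
(944/84 = 11.24), not a mean of per-patient ratios, which would differ.
`max_stage` ranks empty/atretic < GV < MI < PB1; the source never ranks
empty follicles, so the order is an argument. The genotype–phenotype
cross-table buckets residues as pre-p.217, p.217–341, p.342–446 and
post-p.446; compound heterozygotes count once per bucket they hit and are
flagged when double-counted. In the bundled cohort no carrier of a
p.342–446 variant (including the exon-13 splice acceptor, which anchors
to residue 409) reaches PB1, and PB1-positive patients predominantly
carry N-terminal variants.

## Curated fixtures

The bundled 31-site / 34-patient lineage is curated from published counts
rather than copied from a deposited dataset (none exists). Aggregates that
the curated tables reproduce exactly: consequence tally 18/7/3/3;
23/31 = 74.19 % in PAT1; 21/31 = 67.74 % helical; 10/31 non-helical or
intronic; 7/31 = 22.58 % nonsense; exon 13 leading the hotspot ranking
with 6 sites / 9 patients and 7 of 48 encoded residues altered (14.58 %);
944 oocytes split 508/87/139/210; 84 cycles; mean age 31.41 ± 4.34 and
infertility duration 7.00 ± 3.04 years. Three sites are curation
inventions with codon-consistent protein pairs (c.835C>T/p.R279C,
c.1345A>G/p.T449A, and the in-frame two-codon deletion
c.1330_1335del/p.Ile444_Gln445del — required because exon 13 has six
sites but seven altered residues, so one site must span two codons).
Known unreachable printed values: per-exon patient counts for exons 7/10/14
cannot all hold simultaneously under two alleles per patient with the other
printed constraints (the table reports (3,4)/(4,4)/(3,4) against printed
(3,5)/(4,5)/(3,5)); and no integer cycle vector with n = 34 summing to 84
can have sample SD 1.61 (Σx²−Σx is always even), so the bundled cohort's
SD is 1.62 and the printed 2.44 ± 1.61 mean-cycles line is logged as a
discrepancy against the computed 2.47.

Site-level curation notes: the source lists c.T558A as a homozygous
missense change yet pairs the same position with p.Y186*, and c.C784T with
p.R262*; both are stored with the curated "missense" label, classified as
nonsense (stop priority) and flagged. c.A1225+2C and c.865delA appear in
the source's compound-heterozygote prose but are not among the bundled 31
sites: including either would break the printed 3-splicing/3-deletion
tally. c.C805A appears only in the frequency extract.

## Synthetic data generator

`simulate` emulates the statistical structure the analysis assumes:
patient cycles are 1 + Poisson draws around the cohort mean (2.47),
per-cycle oocyte yields Poisson with mean 11.24, stage splits multinomial
at the pooled clinical proportions (53.81/9.22/14.72/22.25 %); allele
frequencies are log-uniform over 10⁻⁶–10⁻²·³ (anchored at the
1-in-150,000 rarity scale of the sparsest reported sites); predictor
scores land beyond each tool's cutoff with a configured exceedance
probability given the latent pathogenic label. One integer seed feeds
deterministic per-generator substreams, so adding a generator never
perturbs another's draws. The generator does not simulate linkage,
population structure, sequence context, or patient-level genotype–
phenotype coupling — passing recovery tests therefore demonstrates
statistical calibration of the pipeline, not clinical realism.

## Numerical conventions

Percentages round half-even to two decimals via Python's `round`.
Ranking ties break deterministically (hotspots: lower exon number;
frequency ranking: lexicographic variant id), and all sorts are stable,
so permuting input rows never changes a report. Allele frequencies given
with counts must satisfy AF = AC/AN within 10⁻¹²; degenerate inputs
(empty cohorts, zero oocytes, frequencies outside [0,1], unresolved
duplicate sites) raise typed errors rather than producing partial output.

## Problem sizes

The bundled analysis is desk-scale (31 + 37 variant sites, 34 patients,
~60 frequency rows) and runs in well under a second; the synthetic
recovery checks use 500-patient cohorts (~13,000 oocytes) and 200-variant
score tables, sizes at which multinomial and binomial sampling error
bands (3 SE) are tight enough to be meaningful.
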