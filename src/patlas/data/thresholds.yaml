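# Per-tool deleteriousness cutoffs for the pathogenicity consensus.
# direction "le": score <= cutoff votes pathogenic; "ge": score >= cutoff.
# Defaults follow each tool's published damaging convention; CADD uses the
# scaled-score cutoff of 10 adopted by the curated analysis. Conservation is
# not listed here: it votes pathogenic when the residue lies inside a
# conserved interval of the gene model.
SIFT:             {cutoff: 0.05, direction: le}
CADD:             {cutoff: 10.0, direction: ge}
REVEL:            {cutoff: 0.5,  direction: ge}
MutationAssessor: {cutoff: 1.9,  direction: ge}
PolyPhen2:        {cutoff: 0.85, direction: ge}
min_votes: 4
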