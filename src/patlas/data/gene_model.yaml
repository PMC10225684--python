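# PATL2 gene model used by the annotation layer.
#
# Coordinates are 1-based inclusive at both ends. The coding coordinate
# system merges two RefSeq transcripts (E1-E2 from NM_001330283.1,
# E3-E16 from NM_001145112.1) into one 1632-nt CDS encoding 543 residues.
# Helix bounds beyond H9/H10 are curated from an AlphaFold-derived secondary
# structure sketch; different predictors disagree on exact bounds, so the
# table is editable and carries no claim of crystallographic precision.
protein_length: 543
provenance: "merged CDS: E1-E2 NM_001330283.1, E3-E16 NM_001145112.1; helices curated from AlphaFold-derived secondary structure"
exons:
  - {label: E1,  cdna_start: 1,    cdna_end: 108,  prot_start: 1,   prot_end: 36}
  - {label: E2,  cdna_start: 109,  cdna_end: 222,  prot_start: 37,  prot_end: 74}
  - {label: E3,  cdna_start: 223,  cdna_end: 354,  prot_start: 75,  prot_end: 118}
  - {label: E4,  cdna_start: 355,  cdna_end: 474,  prot_start: 119, prot_end: 158}
  - {label: E5,  cdna_start: 475,  cdna_end: 540,  prot_start: 159, prot_end: 180}
  - {label: E6,  cdna_start: 541,  cdna_end: 660,  prot_start: 181, prot_end: 220}
  - {label: E7,  cdna_start: 661,  cdna_end: 798,  prot_start: 221, prot_end: 266}
  - {label: E8,  cdna_start: 799,  cdna_end: 876,  prot_start: 267, prot_end: 292}
  - {label: E9,  cdna_start: 877,  cdna_end: 930,  prot_start: 293, prot_end: 310}
  - {label: E10, cdna_start: 931,  cdna_end: 1128, prot_start: 311, prot_end: 376}
  - {label: E11, cdna_start: 1129, cdna_end: 1176, prot_start: 377, prot_end: 392}
  - {label: E12, cdna_start: 1177, cdna_end: 1224, prot_start: 393, prot_end: 408}
  - {label: E13, cdna_start: 1225, cdna_end: 1366, prot_start: 409, prot_end: 456}
  - {label: E14, cdna_start: 1367, cdna_end: 1560, prot_start: 457, prot_end: 520}
  - {label: E15, cdna_start: 1561, cdna_end: 1608, prot_start: 521, prot_end: 536}
  - {label: E16, cdna_start: 1609, cdna_end: 1632, prot_start: 537, prot_end: 543}
domains:
  PAT1:       {start: 252, end: 491}   # mRNA decay factor PAT1 domain
  FUGUE:      {start: 158, end: 534}   # FUGUE (CATH-based) domain
  N_terminal: {start: 1,   end: 239}
  C_terminal: {start: 492, end: 543}
helices:
  - {label: H1,  start: 30,  end: 42}
  - {label: H2,  start: 55,  end: 66}
  - {label: H3,  start: 78,  end: 90}
  - {label: H4,  start: 100, end: 112}
  - {label: H5,  start: 125, end: 138}
  - {label: H6,  start: 150, end: 158}
  - {label: H7,  start: 188, end: 198}
  - {label: H8,  start: 210, end: 225}
  - {label: H9,  start: 252, end: 263}
  - {label: H10, start: 269, end: 277}
  - {label: H11, start: 279, end: 287}
  - {label: H12, start: 291, end: 302}
  - {label: H13, start: 305, end: 320}
  - {label: H14, start: 330, end: 340}
  - {label: H15, start: 348, end: 358}
  - {label: H16, start: 365, end: 382}
  - {label: H17, start: 390, end: 400}
  - {label: H18, start: 410, end: 420}
  - {label: H19, start: 423, end: 430}
  - {label: H20, start: 432, end: 440}
  - {label: H21, start: 446, end: 462}
  - {label: H22, start: 470, end: 483}
  - {label: H23, start: 495, end: 505}
conserved_regions:
  - {start: 201, end: 285}
  - {start: 451, end: 530}
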