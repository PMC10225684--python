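# Values printed in the curated source literature that the pipeline checks
# its own computations against. Wherever a computed value disagrees, the
# report's discrepancy log records both; nothing is silently reconciled.
cohort:
  mean_age: 31.41
  sd_age: 4.34
  mean_infertility_years: 7.00
  sd_infertility_years: 3.04
  mean_cycles: 2.44          # conflicts with 84 cycles / 34 patients = 2.47
  sd_cycles: 1.61
  oocytes_per_cycle: 11.24
stage_percent:
  gv: 53.81
  mi: 9.22
  pb1: 14.72                 # a later summary prints 15.36 for the same data
  empty_atretic: 22.25       # a later summary prints 21.61
stage_percent_alternative:
  pb1: 15.36
  empty_atretic: 21.61
domain_percent:
  pat1: 74.19                # 23/31; an alternative passage prints 70.97 (22/31)
  pat1_alternative: 70.97
  n_terminal_alternative: 16.13
  c_terminal_alternative: 3.23
  helical: 67.74             # 21/31
  non_helical_or_intron: 32.26
  nonsense: 22.58            # 7/31 stop-codon mutations
carrier:
  cumulative_af_reported_per_100k: 48.09
  cumulative_af_database_missense_per_100k: 64.86
  cumulative_af_database_nonsense_per_100k: 3.81
  headline_per_mille: 1.14   # component sum is 116.76/100k ~ 1.17 per mille
  headline_one_in_n: 877
  del13_carrier_per_mille: 0.25
curated_label_conflicts:
  # site-level labels in the curated source that disagree with what the
  # parsed notation implies; the classifier reports the computed label.
  - {variant_id: "c.558T>A", curated: missense, note: "protein change p.Y186* implies nonsense"}
  - {variant_id: "c.784C>T", curated: missense, note: "protein change p.R262* implies nonsense"}
transition_label_conflicts:
  # curated transition-category prose vs standard side-chain chemistry
  - {variant_id: "c.1108G>A", protein: "p.G370R", curated: "polar_uncharged->polar_negative", computed: "nonpolar->polar_positive"}
  - {variant_id: "c.877G>T", protein: "p.D293Y", curated: "polar_positive->polar_uncharged", computed: "polar_negative->polar_uncharged"}
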