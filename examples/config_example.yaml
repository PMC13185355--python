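# Example pdmedalgo configuration: every code set and threshold the
# algorithm uses can be overridden per deployment. Omitted keys keep the
# documented defaults.
codebook:
  # replace or extend semantic code sets (ATC exact-match, ICD-10 prefixes)
  dx_sets:
    pd: ["G20"]
    constipation: ["K59"]
  antipsychotics: [
    "N05AA01", "N05AB02", "N05AD01", "N05AH02", "N05AH03", "N05AH04",
    "N05AX08", "N05AX12", "N05AX13",
  ]

algorithm:
  quetiapine_dose_threshold_mg: 50.0
  missing_quetiapine_strength_counts: true
  min_fpd: "2005-01-01"
  min_age_at_fpd: 25
  max_age_at_fpd: 100
  comt_counts_for_inclusion: true
  anticholinergics_count_for_inclusion: false
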