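# Clinical evidence and perspective constants for the base-case model.
# Survival landmarks and hazard ratios are 3-year (36-month) values from
# the ENZAMET trial of enzalutamide added to first-line testosterone
# suppression in metastatic hormone-sensitive prostate cancer; adverse
# events are grade 3-4 with incidence >= 5% in at least one arm.
landmark_time_months: 36

landmarks:
  OS:
    enzalutamide: 0.80
    standard_care: 0.72
  PSA_PFS:
    enzalutamide: 0.67
    standard_care: 0.37
  clinical_PFS:
    enzalutamide: 0.68
    standard_care: 0.41

# Enzalutamide vs standard care.
hazard_ratios:
  OS: 0.67
  PSA_PFS: 0.39
  clinical_PFS: 0.40

# Cumulative incidence of grade 3-4 adverse events, as fractions.
ae_incidence:
  enzalutamide:
    febrile_neutropenia: 0.07
    hypertension: 0.08
    neutrophil_count_decreased: 0.06
    fatigue: 0.06
  standard_care:
    febrile_neutropenia: 0.06
    hypertension: 0.04
    neutrophil_count_decreased: 0.03
    fatigue: 0.01

perspectives:
  US:
    annual_discount_rate: 0.035
    wtp_per_qaly: 100000.00
    utility_pfs: 0.83
    utility_pd: 0.725
    bsa: 2.1
  China:
    annual_discount_rate: 0.03
    wtp_per_qaly: 28988.40   # 3x per-capita GDP of China, 2018, in USD
    utility_pfs: 0.76
    utility_pd: 0.68
    bsa: 1.72
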