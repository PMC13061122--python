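fecundability_beta:
  beta_a: 0.9
  beta_b: 3.6
  scale: 1.0
treatment_mean_rates:
  IUI: 0.015
  IVF: 0.24
  ICSI: 0.24
  FET: 0.17
treatment_multiple_means:
  IUI: 0.08
  IVF: 0.15
  ICSI: 0.15
  FET: 0.07
natural_multiple_mean: 0.015
twin_triplet_counts:
- 9700
- 300
education_distribution:
  primary: 0.25
  secondary: 0.4
  tertiary: 0.35
intended_family_size_distribution:
  0: 0.1
  1: 0.15
  2: 0.5
  3: 0.19
  4: 0.06
contraception:
  monthly_failure: 0.004
  abortion_probability: 0.5
uptake:
  mean: 0.73
  n: 825
  draws: 10000
thresholds:
  art_fecundability_gate: 0.0077
  entry_cum12_threshold: 0.58
  entry_check_max_age_years: 38
  diagnosis_min_months_trying: 12
  max_age_at_mar_years: 43
  max_iui_cycles: 6
  max_ivf_icsi_cycles: 3
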