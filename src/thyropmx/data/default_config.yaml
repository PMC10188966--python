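# Packaged default configuration: the published population parameter table
# for FT4 dynamics in pediatric Graves' disease under CMZ / CMZ+LT4 therapy,
# plus the virtual-cohort generator defaults calibrated to that study cohort.

pk:
  kaC: 144.0        # CMZ absorption rate (1/day), fixed
  kt: 28.8          # metabolic transit rate (1/day), fixed
  fM: 0.61          # CMZ -> MMZ conversion factor, fixed
  kelM: 2.77        # MMZ elimination rate (1/day), 6 h half-life, fixed
  k12: 2.4          # distribution rate to peripheral compartment (1/day), fixed
  k21: 2.4          # distribution rate from peripheral compartment (1/day), fixed
  fVM: 0.5          # MMZ volume of distribution per kg body weight (l/kg), fixed
  FC: 0.61          # simplified-model dose scaling factor (= fM)

pd:
  kaT4: 20.0        # LT4 absorption rate (1/day), fixed
  kendoT4: 261.0    # endogenous T4 production rate (nmol/day), estimated
  kelT4: 0.1        # T4 elimination rate (1/day), fixed
  Imax: 0.9         # maximal inhibitory effect, fixed
  IC50: 0.024       # MMZ concentration at half-maximal inhibition (mg/l), estimated
  fVT4: 20.3        # T4 volume multiplicative factor (l), estimated
  beta: 0.7         # allometric power exponent, estimated
  FT4bio: 0.6       # LT4 bioavailability, fixed
  WRef: 42.7        # reference body weight (kg)
  lt4_factor: 1.29  # LT4 mcg -> nmol conversion

population:
  beta_age: 0.464            # age effect on log kendoT4
  beta_cat1_severe: 0.52     # severe-vs-mild effect on log kendoT4
  beta_cat2_moderate: 0.16   # moderate-vs-mild effect on log kendoT4
  AGERef: 8.98               # reference age (years)
  omega_kendo: 0.04          # SD of the kendoT4 random effect
  omega_ic50: 0.77           # SD of the IC50 random effect
  omega_fvt4: 0.1            # SD of the fVT4 random effect, fixed
  omega_beta: 0.25           # SD of the beta random effect, fixed
  sigma_prop: 0.344          # proportional residual error SD

cohort:
  n_patients: 44
  p_female: 0.75
  cmz_start_per_kg: 0.72     # mg/kg/day, tid
  p_switch: 0.38636363636363635
  switch_day_median: 75.0
  lt4_start_per_kg: 1.86     # mcg/kg/day, once daily
  cmz_at_switch_per_kg: 0.42
  followup_years_median: 1.89
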