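# Default follicular-lymphoma parameterization.
#
# Attribute distributions (age-band Betas/Dirichlets), utilities and unit
# costs carry the published registry-derived values; entries marked
# `fixture: true` (all time-to-event specifications, the DLBCL add-on, the
# diagnostic bundle and resource-frequency defaults) are documented
# placeholders whose empirical counterparts are not publicly available.
# Times are in days (1 year = 365.25 days); ages in years; costs in 2016 GBP.
age:
  max: 100
  min: 18
  spec:
    family: weibull
    params:
    - 5.57
    - 69.33
age_bands:
- label: <=30
  lower: 18
  male:
    alpha: 4
    beta: 1
  management:
    alphas:
    - 2
    - 0
    - 1
    - 2
    - 0
  upper: 30
  ww_rituximab:
    alpha: 0
    beta: 2
- label: 30-40
  lower: 30
  male:
    alpha: 15
    beta: 10
  management:
    alphas:
    - 14
    - 2
    - 1
    - 8
    - 0
  upper: 40
  ww_rituximab:
    alpha: 0
    beta: 8
- label: 40-50
  lower: 40
  male:
    alpha: 44
    beta: 35
  management:
    alphas:
    - 36
    - 4
    - 6
    - 32
    - 1
  upper: 50
  ww_rituximab:
    alpha: 0
    beta: 32
- label: 50-60
  lower: 50
  male:
    alpha: 69
    beta: 86
  management:
    alphas:
    - 73
    - 21
    - 7
    - 54
    - 0
  upper: 60
  ww_rituximab:
    alpha: 1
    beta: 53
- label: 60-70
  lower: 60
  male:
    alpha: 95
    beta: 120
  management:
    alphas:
    - 97
    - 22
    - 11
    - 81
    - 4
  upper: 70
  ww_rituximab:
    alpha: 3
    beta: 78
- label: 70-80
  lower: 70
  male:
    alpha: 82
    beta: 93
  management:
    alphas:
    - 74
    - 12
    - 10
    - 77
    - 2
  upper: 80
  ww_rituximab:
    alpha: 1
    beta: 76
- label: '>=80'
  lower: 80
  male:
    alpha: 27
    beta: 59
  management:
    alphas:
    - 34
    - 2
    - 5
    - 39
    - 6
  upper: null
  ww_rituximab:
    alpha: 0
    beta: 39
costs:
  allogeneic_sct: 46608
  autograft_sct: 5786
  chemo_cycle:
    bendamustine: 5089
    chlorambucil: 102
    chop: 303
    cvp: 300
    dhap: 609
    r_bendamustine: 6855
    r_chlorambucil: 1867
    r_chop: 1817
    r_cvp: 1560
    r_dhap: 2050
    r_eshap: 3511
  diagnostic_workup: 1200
  end_of_life_daily: 80
  excess_bed_day: 232
  gbp_to_usd: 1.2505
  inpatient_spell: 759
  outpatient_first_multi: 463
  outpatient_first_single: 288
  outpatient_followup_multi: 216
  outpatient_followup_single: 120
  radiotherapy_fraction: 120
  radiotherapy_planning: 769
  rituximab_administration: 1260
discount_rate: 0.035
dlbcl_addon:
  cost: 22000
  fixture: true
  life_years: 11.5
  qalys: 8.0
flipi:
  alphas:
  - 1
  - 1
  - 1
incidence_per_year: 1860
induction_administrations: 4
monitoring_visits_per_year: 4
radiotherapy:
  fractions_ia: 15
  fractions_palliative: 5
regimens:
  cycles_default: 6
  cycles_per_regimen: {}
  mix:
    '1':
      chlorambucil: 0.08
      chop: 0.05
      cvp: 0.1
      r_chlorambucil: 0.07
      r_chop: 0.25
      r_cvp: 0.45
    '2':
      bendamustine: 0.1
      r_bendamustine: 0.3
      r_chlorambucil: 0.1
      r_chop: 0.4
      r_cvp: 0.1
    '3':
      dhap: 0.2
      r_bendamustine: 0.2
      r_dhap: 0.3
      r_eshap: 0.3
sct:
  autograft_prob:
    alpha: 3
    beta: 1
  prob:
    alpha: 77
    beta: 499
stage_ia:
  alpha: 74
  beta: 666
transitions:
  end_of_life_death:
    family: exponential
    fixture: true
    params:
    - 0.0133333333
  pretreatment_to_management:
    family: lognormal
    fixture: true
    params:
    - 3.044522
    - 0.5
  remission1_death:
    family: weibull
    fixture: true
    params:
    - 1.5
    - 5113.5
  remission1_relapse:
    family: weibull
    fixture: true
    params:
    - 1.1
    - 4383.0
  remission1_transform:
    family: exponential
    fixture: true
    params:
    - 7.82243e-05
  remission2_death:
    family: weibull
    fixture: true
    params:
    - 1.4
    - 3652.5
  remission2_relapse:
    family: weibull
    fixture: true
    params:
    - 1.0
    - 2191.5
  remission2_transform:
    family: exponential
    fixture: true
    params:
    - 7.82243e-05
  remission3_death:
    family: weibull
    fixture: true
    params:
    - 1.3
    - 2556.75
  remission3_relapse:
    family: weibull
    fixture: true
    params:
    - 1.0
    - 1461.0
  remission3_transform:
    family: exponential
    fixture: true
    params:
    - 7.82243e-05
  treatment1_death:
    family: exponential
    fixture: true
    params:
    - 0.0003422313
  treatment1_refractory:
    family: exponential
    fixture: true
    params:
    - 0.0006844627
  treatment1_response:
    family: lognormal
    fixture: true
    params:
    - 4.85076
    - 0.4
  treatment1_transform:
    family: exponential
    fixture: true
    params:
    - 9.12617e-05
  treatment2_death:
    family: exponential
    fixture: true
    params:
    - 0.0004563085
  treatment2_refractory:
    family: exponential
    fixture: true
    params:
    - 0.0009126169
  treatment2_response:
    family: lognormal
    fixture: true
    params:
    - 4.85076
    - 0.4
  treatment2_transform:
    family: exponential
    fixture: true
    params:
    - 9.12617e-05
  treatment3_death:
    family: exponential
    fixture: true
    params:
    - 0.0006844627
  treatment3_refractory:
    family: exponential
    fixture: true
    params:
    - 0.0013689254
  treatment3_response:
    family: lognormal
    fixture: true
    params:
    - 4.85076
    - 0.45
  treatment3_transform:
    family: exponential
    fixture: true
    params:
    - 9.12617e-05
  ww_to_death:
    family: weibull
    fixture: true
    params:
    - 1.4
    - 4017.75
  ww_to_transform:
    family: exponential
    fixture: true
    params:
    - 6.84463e-05
  ww_to_treatment:
    family: lognormal
    fixture: true
    params:
    - 6.816873
    - 1.6
utilities:
  first_line_treatment:
    alpha: 291.95
    beta: 59.8
  first_remission:
    alpha: 928.4
    beta: 126.6
  not_treated:
    alpha: 34.2
    beta: 34.2
  pretreatment:
    alpha: 31.7
    beta: 6.49
  subsequent_remission:
    alpha: 144.83
    beta: 38.5
  subsequent_treatment:
    alpha: 161.68
    beta: 99.1
  ww:
    alpha: 270.1
    beta: 47.66
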