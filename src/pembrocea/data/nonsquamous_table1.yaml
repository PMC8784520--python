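# Model inputs, non-squamous metastatic NSCLC with PD-L1 >= 50%.
# Point values, sensitivity ranges and PSA distribution families for every
# input of the cost-effectiveness model (2021 USD).  Regimen blocks encode
# standard-of-care dosing for the two strategies; vial sizes are US
# single-use presentations.
histology: non_squamous

parameters:
  # --- survival: log-logistic S(t) = 1/(1 + theta * t^kappa), t in months
  theta_os:  {value: 0.03084, dist: fixed}
  kappa_os:  {value: 0.92588, dist: fixed}
  theta_pfs: {value: 0.01422, dist: fixed}
  kappa_pfs: {value: 1.80138, dist: fixed}

  # hazard ratios, pembrolizumab monotherapy vs pembrolizumab+chemotherapy
  hr_os:  {value: 1.67, low: 0.46, high: 2.87, dist: lognormal, kind: hr}
  hr_pfs: {value: 1.53, low: 0.24, high: 2.86, dist: lognormal, kind: hr}

  # per-cycle probability of treatment discontinuation due to AEs
  disc_pembro_mono:     {value: 0.005559, low: 0.002779, high: 0.008338, dist: beta, kind: probability}
  disc_pembro_combo:    {value: 0.010231, low: 0.005115, high: 0.015346, dist: beta, kind: probability}
  disc_pemetrexed:      {value: 0.011788, low: 0.005894, high: 0.017682, dist: beta, kind: probability}
  disc_platinum:        {value: 0.003613, low: 0.001807, high: 0.005420, dist: beta, kind: probability}

  # --- costs (USD)
  price_pembrolizumab_mg:  {value: 52.75, low: 26.38, high: 79.13, dist: gamma, kind: cost}
  price_pemetrexed_mg:     {value: 7.49,  low: 3.75,  high: 11.24, dist: gamma, kind: cost}
  price_carboplatin_mg:    {value: 0.05,  low: 0.03,  high: 0.08,  dist: gamma, kind: cost}
  price_cisplatin_mg:      {value: 0.18,  low: 0.09,  high: 0.27,  dist: gamma, kind: cost}
  infusion_first_hour:     {value: 148.30, low: 74.15, high: 222.45, dist: gamma, kind: cost}
  infusion_additional_hour: {value: 31.40, low: 15.70, high: 47.10,  dist: gamma, kind: cost}
  physician_visit:         {value: 183.19, low: 91.60, high: 274.79, dist: gamma, kind: cost}
  imaging:                 {value: 117.59, low: 58.80, high: 176.39, dist: gamma, kind: cost}
  bsc_cost:                {value: 637.0,  low: 318.50, high: 955.50, dist: gamma, kind: cost}
  death_cost:              {value: 9433.0, low: 4716.50, high: 14149.50, dist: gamma, kind: cost}
  ae_cost_pembro:          {value: 1400.88, low: 700.44,  high: 2101.31, dist: gamma, kind: cost}
  ae_cost_pembro_chemo:    {value: 6142.07, low: 3071.03, high: 9213.10, dist: gamma, kind: cost}
  subsequent_cost_pembro:       {value: 12283.0, low: 6141.50, high: 18424.50, dist: gamma, kind: cost}
  subsequent_cost_pembro_chemo: {value: 12831.0, low: 6415.50, high: 19246.50, dist: gamma, kind: cost}

  # --- utilities by time-to-death window
  u_ge12: {value: 0.834, low: 0.823, high: 0.846, dist: beta, kind: utility}
  u_6_12: {value: 0.765, low: 0.743, high: 0.786, dist: beta, kind: utility}
  u_1_6:  {value: 0.709, low: 0.690, high: 0.728, dist: beta, kind: utility}
  u_le1:  {value: 0.563, low: 0.461, high: 0.665, dist: beta, kind: utility}

  # aggregate grade >=3 AE disutility (utility units; applied over
  # ae_duration_months as a one-off QALY decrement at model entry)
  disutility_pembro:       {value: 0.016, low: 0.008, high: 0.024, dist: beta, kind: utility}
  disutility_pembro_chemo: {value: 0.098, low: 0.049, high: 0.148, dist: beta, kind: utility}
  ae_duration_months:      {value: 1.0, dist: fixed}

  # --- patient characteristics and analysis settings
  bsa:           {value: 1.79, low: 1.78, high: 1.80, dist: normal}
  crcl:          {value: 70.0, low: 35.0, high: 105.0, dist: normal}
  discount_rate: {value: 0.03, low: 0.0, high: 0.05, dist: normal}

  # proportion of progressing patients who receive subsequent anticancer
  # therapy (the remainder receive a best-supportive-care package)
  subsequent_uptake: {value: 0.5, dist: fixed, kind: probability}

  # fatal treatment-related AE probabilities used only by the
  # background-mortality scenario; illustrative trial-scale values
  fatal_ae_pembro:       {value: 0.006, dist: fixed, kind: probability}
  fatal_ae_pembro_chemo: {value: 0.067, dist: fixed, kind: probability}
  start_age:             {value: 65.0, dist: fixed}

regimens:
  pembro:
    drugs:
      - name: pembrolizumab
        dose: {type: flat, value: 200}
        interval_days: 21
        max_administrations: 35
        infusion_hours: 0.5
        vial_sizes_mg: [100]
        price_param: price_pembrolizumab_mg
        discontinuation_param: disc_pembro_mono
  pembro_chemo:
    drugs:
      - name: pembrolizumab
        dose: {type: flat, value: 200}
        interval_days: 21
        max_administrations: 35
        infusion_hours: 0.5
        vial_sizes_mg: [100]
        price_param: price_pembrolizumab_mg
        discontinuation_param: disc_pembro_combo
      - name: pemetrexed            # 500 mg/m2 q3w, maintenance until progression
        dose: {type: per_m2, value: 500}
        interval_days: 21
        infusion_hours: 0.5
        vial_sizes_mg: [100, 500]
        price_param: price_pemetrexed_mg
        discontinuation_param: disc_pemetrexed
      - name: carboplatin           # AUC 5 q3w, 4 induction cycles
        dose: {type: auc, value: 5}
        interval_days: 21
        max_administrations: 4
        infusion_hours: 1.0
        vial_sizes_mg: [50, 150, 450, 600]
        price_param: price_carboplatin_mg
        discontinuation_param: disc_platinum
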