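# Model inputs, squamous metastatic NSCLC with PD-L1 >= 50%.
# Same structure as the non-squamous file; survival shapes, hazard ratios,
# discontinuation probabilities, AE aggregates, subsequent-therapy costs
# and utilities are histology-specific.
histology: squamous

parameters:
  theta_os:  {value: 0.02428, dist: fixed}
  kappa_os:  {value: 1.27621, dist: fixed}
  theta_pfs: {value: 0.00985, dist: fixed}
  kappa_pfs: {value: 2.25359, dist: fixed}

  hr_os:  {value: 1.13, low: 0.60, high: 2.10, dist: lognormal, kind: hr}
  hr_pfs: {value: 1.06, low: 0.14, high: 1.81, dist: lognormal, kind: hr}

  disc_pembro_mono:  {value: 0.005559, low: 0.002779, high: 0.008338, dist: beta, kind: probability}
  disc_pembro_combo: {value: 0.011023, low: 0.005512, high: 0.016535, dist: beta, kind: probability}
  disc_paclitaxel:   {value: 0.010025, low: 0.005013, high: 0.015038, dist: beta, kind: probability}
  disc_carboplatin:  {value: 0.006890, low: 0.003445, high: 0.010336, dist: beta, kind: probability}

  price_pembrolizumab_mg:   {value: 52.75, low: 26.38, high: 79.13, dist: gamma, kind: cost}
  price_paclitaxel_mg:      {value: 0.13,  low: 0.07,  high: 0.20,  dist: gamma, kind: cost}
  price_nab_paclitaxel_mg:  {value: 14.08, low: 7.04,  high: 21.12, dist: gamma, kind: cost}
  price_carboplatin_mg:     {value: 0.05,  low: 0.03,  high: 0.08,  dist: gamma, kind: cost}
  price_cisplatin_mg:       {value: 0.18,  low: 0.09,  high: 0.27,  dist: gamma, kind: cost}
  infusion_first_hour:      {value: 148.30, low: 74.15, high: 222.45, dist: gamma, kind: cost}
  infusion_additional_hour: {value: 31.40,  low: 15.70, high: 47.10,  dist: gamma, kind: cost}
  physician_visit:          {value: 183.19, low: 91.60, high: 274.79, dist: gamma, kind: cost}
  imaging:                  {value: 117.59, low: 58.80, high: 176.39, dist: gamma, kind: cost}
  bsc_cost:                 {value: 637.0,  low: 318.50, high: 955.50, dist: gamma, kind: cost}
  death_cost:               {value: 9433.0, low: 4716.50, high: 14149.50, dist: gamma, kind: cost}
  ae_cost_pembro:           {value: 1400.88, low: 700.44,  high: 2101.31, dist: gamma, kind: cost}
  ae_cost_pembro_chemo:     {value: 5932.63, low: 2966.31, high: 8898.94, dist: gamma, kind: cost}
  subsequent_cost_pembro:       {value: 3785.0, low: 1892.50, high: 5677.50, dist: gamma, kind: cost}
  subsequent_cost_pembro_chemo: {value: 1195.0, low: 597.50,  high: 1792.50, dist: gamma, kind: cost}

  u_ge12: {value: 0.842, low: 0.823, high: 0.861, dist: beta, kind: utility}
  u_6_12: {value: 0.814, low: 0.795, high: 0.833, dist: beta, kind: utility}
  u_1_6:  {value: 0.737, low: 0.717, high: 0.756, dist: beta, kind: utility}
  u_le1:  {value: 0.568, low: 0.481, high: 0.655, dist: beta, kind: utility}

  disutility_pembro:       {value: 0.016, low: 0.008, high: 0.024, dist: beta, kind: utility}
  disutility_pembro_chemo: {value: 0.105, low: 0.053, high: 0.158, dist: beta, kind: utility}
  ae_duration_months:      {value: 1.0, dist: fixed}

  bsa:           {value: 1.79, low: 1.78, high: 1.80, dist: normal}
  crcl:          {value: 70.0, low: 35.0, high: 105.0, dist: normal}
  discount_rate: {value: 0.03, low: 0.0, high: 0.05, dist: normal}

  subsequent_uptake: {value: 0.5, dist: fixed, kind: probability}

  fatal_ae_pembro:       {value: 0.006, dist: fixed, kind: probability}
  fatal_ae_pembro_chemo: {value: 0.036, dist: fixed, kind: probability}
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
      - name: paclitaxel            # 200 mg/m2 q3w, 4 cycles
        dose: {type: per_m2, value: 200}
        interval_days: 21
        max_administrations: 4
        infusion_hours: 3.0
        vial_sizes_mg: [30, 100, 300]
        price_param: price_paclitaxel_mg
        discontinuation_param: disc_paclitaxel
      - name: carboplatin           # AUC 6 q3w, 4 cycles
        dose: {type: auc, value: 6}
        interval_days: 21
        max_administrations: 4
        infusion_hours: 1.0
        vial_sizes_mg: [50, 150, 450, 600]
        price_param: price_carboplatin_mg
        discontinuation_param: disc_carboplatin
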