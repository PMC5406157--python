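# Default evidence base and economic settings for the childhood-UTI
# diagnostic cost-effectiveness model.
#
# Each entry under `parameters` is a named sampling law:
#   binomial-proportion: successes/trials; point estimate successes/trials,
#                        PSA draw Beta(successes+1, failures+1) (flat prior).
#   lognormal-odds:      log_mean/log_sd on the log-odds scale; point estimate
#                        exp(m)/(1+exp(m)); PSA draw exp(N(m,s)) -> probability.
#   lognormal-rr:        log_mean/log_sd on the log relative-risk scale.
#   uniform:             lower/upper; point estimate the midpoint.
#   triangle:            lower/mode/upper; point estimate the mean.
#   fixed:               value.
# An optional `estimate` overrides the computed point estimate where the
# published rounding convention differs from the raw ratio.
#
# All monetary values are GBP at 2014/15 prices.

price_year: "2014/15"

parameters:
  # --- short-term model ---
  uti_prevalence:            {law: binomial-proportion, successes: 60,    trials: 2676}   # 0.022
  pa_given_uti:              {law: binomial-proportion, successes: 9,     trials: 55}     # 0.164
  vur_given_uti:             {law: lognormal-odds, log_mean: -1.153, log_sd: 0.113}       # 0.240
  very_unwell:               {law: binomial-proportion, successes: 133,   trials: 2676}   # 0.050
  urine_sample_obtained:     {law: binomial-proportion, successes: 2231,  trials: 2332}   # 0.957
  contamination:             {law: binomial-proportion, successes: 140,   trials: 2619, estimate: 0.046}
  resistance_amoxicillin:    {law: binomial-proportion, successes: 50,    trials: 94, estimate: 0.531}
  resistance_trimethoprim:   {law: binomial-proportion, successes: 26,    trials: 94}     # 0.277
  reconsultation:            {law: binomial-proportion, successes: 42,    trials: 222}    # 0.189
  antibiotics_for_non_uti:   {law: binomial-proportion, successes: 78,    trials: 262, estimate: 0.294}
  stop_antibiotic_no_uti:    {law: uniform, lower: 0.05, upper: 0.10}                     # 0.075
  referred_for_us:           {law: binomial-proportion, successes: 6,     trials: 103, estimate: 0.059}
  dipstick_lorn_sensitivity: {law: binomial-proportion, successes: 46,    trials: 60}     # 0.767 (leuk OR nitrite)
  dipstick_lorn_specificity: {law: binomial-proportion, successes: 2200,  trials: 2616}   # 0.841
  dipstick_land_sensitivity: {law: binomial-proportion, successes: 22,    trials: 60}     # 0.367 (leuk AND nitrite)
  dipstick_land_specificity: {law: binomial-proportion, successes: 2588,  trials: 2616}   # 0.989
  lab_sensitivity:           {law: binomial-proportion, successes: 45,    trials: 57}     # 0.789
  lab_specificity:           {law: binomial-proportion, successes: 2341,  trials: 2398}   # 0.976
  us_sensitivity:            {law: lognormal-odds, log_mean: -0.243, log_sd: 0.235}       # 0.440
  us_specificity:            {law: lognormal-odds, log_mean: 1.238,  log_sd: 0.286}       # 0.775
  mcug_sensitivity:          {law: fixed, value: 1.0}
  mcug_specificity:          {law: fixed, value: 1.0}
  treatment_effect:          {law: lognormal-rr, log_mean: -0.599, log_sd: 0.247}         # 0.550
  resistant_effect_multiplier: {law: uniform, lower: 0.5, upper: 0.9}                     # 0.700
  # --- medium-term model ---
  consult_no_uti:            {law: binomial-proportion, successes: 21193, trials: 30588}  # 0.693
  consult_uti_no_history:    {law: binomial-proportion, successes: 9.33,  trials: 2789}   # 0.003
  consult_uti_history:       {law: lognormal-odds, log_mean: -2.442, log_sd: 0.218}       # 0.080
  vur_treatment_effect:      {law: lognormal-rr, log_mean: -0.385, log_sd: 0.280}         # 0.68
  # --- long-term model ---
  prs_0pa:                   {law: binomial-proportion, successes: 7,     trials: 141}    # 0.050
  prs_1pa:                   {law: binomial-proportion, successes: 32,    trials: 366}    # 0.087
  prs_2pa:                   {law: binomial-proportion, successes: 15,    trials: 93}     # 0.161
  prs_3pa:                   {law: binomial-proportion, successes: 12,    trials: 35}     # 0.343
  prs_4pa:                   {law: binomial-proportion, successes: 14,    trials: 24}     # 0.583
  esrd_given_prs:            {law: fixed, value: 0.050}
  esrd_onset_age:            {law: triangle, lower: 7.0, mode: 10.01, upper: 24.0}        # mean 13.67
  transplant_fraction:       {law: fixed, value: 0.5}
  survival_no_esrd:          {law: uniform, lower: 69.4, upper: 76.7, estimate: 73.00}
  survival_dialysis:         {law: uniform, lower: 11.6, upper: 12.9}                     # 12.25
  survival_transplant:       {law: uniform, lower: 20.5, upper: 22.7}                     # 21.60

economics:
  willingness_to_pay: 20000.0        # GBP per QALY
  discount_rate: 0.035               # per year, year 0 undiscounted
  days_per_year: 365.25
  annual_cohort_size: 4654000        # acutely unwell under-5s presenting to UK primary care per year
  costs:
    urine_sample: 7.03               # 9.1 min of practice time, no dipstick
    urine_sample_dipstick: 8.10      # 12.0 min, sample plus point-of-care dipstick
    lab_culture: 3.19                # NHS laboratory culture
    lab_interpretation: 2.42         # 45 s of GP time reading the report
    revision_call: 16.08             # 5 min call to start/stop/change a prescription
    antibiotic_trimethoprim: 2.07    # course, 50 mg/5 ml suspension
    antibiotic_amoxicillin: 1.67     # course, 125 mg/5 ml suspension
    gp_consultation: 31.00           # surgery consultation (index or repeat)
    hospital_episode: 180.0          # paediatric assessment following referral
    ultrasound: 55.0
    mcug: 121.0
    prophylaxis_annual: 41.0         # prophylactic antibiotics for confirmed VUR
    dialysis_annual: 24000.0
    transplant: 20000.0
  utilities:
    asymptomatic: 1.0
    symptomatic_non_uti: 0.942
    symptomatic_uti: 0.942
    pyelonephritis: 0.87
    hospital: 0.87
    baseline: 0.947                  # long-run utility while free of ESRD
    dialysis: 0.55
    transplant: 0.76

resolution:
  # Weibull time-to-resolution defaults; the non-UTI and treated-UTI curves
  # emulate diary fits, the untreated-UTI curve applies the treatment-effect
  # ratio to the treated hazard inside the 7-day effect window.
  non_uti:       {shape: 1.45, scale: 4.50}
  untreated_uti: {shape: 1.30, scale: 9.00}
  pyelonephritis_hazard_multiplier: 0.6
  delayed_window_days: 2
  effect_persistence_days: 7
  horizon_days: 21
  diary_days: 14

horizons:
  medium_term_years: 3

acute_states:
  # Nine-state acute state space; order is load-bearing for the transition
  # structure (asymptomatic is absorbing within the 21-day horizon).
  - asymptomatic
  - symptomatic_non_uti
  - uti_untreated
  - uti_treated_sensitive
  - uti_treated_resistant
  - uti_delayed_window
  - pyelonephritis_untreated
  - pyelonephritis_treated
  - hospital
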