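# Two-stage Bayesian hierarchical basket design, as published.
# Per-cohort historical-control (p_null) and design-alternative (p_alt) pCR
# rates; stage sizes; minimum stage-1 responders to continue ("more than 2 of
# 11" colon, "more than 3 of 8" rectum).
cohorts:
  colon:
    p_null: 0.03
    p_alt: 0.15
    n_stage1: 11
    n_total: 28
    go_min_responders: 3
  rectum:
    p_null: 0.10
    p_alt: 0.35
    n_stage1: 8
    n_total: 16
    go_min_responders: 4
alpha: 0.05
target_power: 0.80
# "joint": both cohorts must clear their stage-1 bar for either to continue
# (the literal published rule); "per_cohort": each cohort continues on its own
# bar (sensitivity analysis).
continuation: joint
prior:
  mu_mean: 0.0
  mu_sd: 10.0
  tau_scale: 1.0
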