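# Simulation configuration for `twinace simulate` / `twinace run`.
# Every key is optional; the values below are the defaults, which
# reproduce the targeted cohort shape (75 MZ pairs, 170 DZ pairs,
# 7 singletons, ages 41-77 with MZ on average 2 years older, and
# 29 two-timepoint longitudinal controls, 14 of them replicated).

n_mz_pairs: 75
n_dz_pairs: 170
n_singletons: 7
age_range: [41.0, 77.0]
mz_age_offset: 2.0

n_traits: 40
# Per-trait variance fractions. Give all three (scalars or per-trait
# lists summing to 1), or omit all three to draw each trait from the
# default AE/CE/ACE mixture.
# a2: 0.6
# c2: 0.2
# e2: 0.2

age_effect_slope: 0.01        # per-year effect on the standardized scale
trait_kind_mix: 0.983         # fraction of CSF (vs SPEL) traits

# Monotone latent-to-observed maps
csf_logit_location: -2.0      # logistic onto (0, 100) percent
csf_logit_scale: 1.0
spel_log_location: 6.0        # exponential onto positive intensities
spel_log_scale: 0.5

# Longitudinal controls
n_controls: 29
n_replicated_controls: 14
measurement_error_sd: 0.3333333333333333   # => test-retest r = 0.9

missing_rate: 0.0
rng_seed: 0
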