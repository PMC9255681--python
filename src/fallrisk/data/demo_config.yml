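# Demonstration configuration: a 5,000-patient synthetic cohort with 25
# bootstrap samples per Bolasso run. The inner cross-validation and penalty
# grid are trimmed relative to the library defaults so the complete pipeline
# (development, 10-fold nested validation and both sensitivity variants) runs
# end to end in a few minutes on one CPU.
n_patients: 5000
seed: 0
bolasso:
  n_bootstrap: 25
  inner_cv_folds: 4
  nlambda: 20
cv_folds: 10
thresholds: [1.0, 0.8]
sensitivity_variants: true
plot: false
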