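# Example TrialScenario overrides for `ceatrial simulate --config ...`.
# Omitted fields keep the package defaults (the emulated study conditions:
# 17 schools/arm x 78 students, ICC .01 weekly / .06 binge, arm effects
# 0.73 glasses/week and 0.49 binge occasions, ~3.5% contamination, ~70%
# covariate-dependent dropout).
n_clusters_per_arm: 17
cluster_size_mean: 78
icc_weekly: 0.01
icc_binge: 0.06
arm_effect_weekly: 0.73
arm_effect_binge: 0.49
contamination_rate: 0.035
dropout_rate: 0.70
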