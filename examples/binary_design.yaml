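# Binary-outcome design: dominant SNP analyzed under its true coding.
maf: 0.1
effect_size: 1.5        # odds ratio per unit of the true-model coded genotype
outcome_type: binary
true_model: dominant_binary
analysis_model: dominant_binary
prevalence: 0.1
baseline_or: 10
n: 3000
alpha: 0.05
target_power: 0.8
reps: 1000
seed: 1
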