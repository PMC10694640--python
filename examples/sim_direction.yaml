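# Week-long cohort whose fall outcomes follow the published sign pattern:
# risk increases with gait quantity (total steps), intensity (cadence) and
# variability (CoV of stride time), and decreases with complexity (DFA and
# sample entropy). Coefficients are on the standardized true-parameter scale.
n_participants: 300
days: 7
seed: 42
true_beta:
  total_steps: 0.4
  cadence: 0.6
  cov_stride_time: 0.5
  dfa_step: -0.8
  sampen_step: -0.6
  sampen_stride: -0.6
nb_dispersion: 1.0
group_beta: 0.0
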