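# Null cohort: fall counts are independent of every gait parameter
# (all true coefficients zero). Cross-validated AUC should sit near 0.5.
n_participants: 300
days: 7
seed: 42
true_beta: {}
nb_dispersion: 1.0
group_beta: 0.0
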