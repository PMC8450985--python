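# Desk-scale demo: 20 participants, reduced MCMC schedule (~3 min).
# The full study design uses the defaults: 222 participants,
# 3 chains x 15000 iterations with 6000 burn-in.
master_seed: 11
synthetic:
  n_participants: 20
models: [M1_start, M2_drift, M3_both]
n_chains: 2
n_iter: 900
burn_in: 400
n_posterior_predictive: 20
bridge_repetitions: 3
plausible_n_draws: 500
plausible_parameters: [start_effect, alpha]
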