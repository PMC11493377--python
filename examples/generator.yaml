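# Paper-like synthetic cohort: 161 knees, five instruments, ~13% failures.
n: 161
seed: 7
outcome_prom: womac_pain
latent_weight: 0.75
target_failure_rate: 0.1304
proms:
  womac_pain:      {location: 3.0,  spread: 3.5, beta1: 0.5}
  womac_stiffness: {location: 1.0,  spread: 1.6}
  womac_function:  {location: 9.0,  spread: 9.0}
  kujala:          {location: 73.0, spread: 15.0}
  koos_ql:         {location: 62.0, spread: 20.0}
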