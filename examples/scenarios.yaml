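scenarios:
  # strong effect: thresholds should bracket the true crossing score
  - {name: strong_effect, prom: womac_pain, n: 5000, location: 8.0, spread: 4.0,
     beta0: -4.0, beta1: 0.30, replicates: 50}
  # null slope: the rule should mostly report no threshold at all
  - {name: null_slope, prom: womac_pain, n: 2000, location: 8.0, spread: 4.0,
     beta0: -1.9, beta1: 0.0, replicates: 50}
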