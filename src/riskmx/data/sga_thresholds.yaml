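# Small-for-gestational-age screening at the 10th vs 5th growth centile.
# Event probabilities are screening prevalences in percent; weights are
# the neonatal outcome distribution (primary care / <2d hospital / >=2d
# hospital / disability / death) in percent of screen-positive neonates.
schema: 1
tolerance: 0.5
scenarios:
  sga-p10:
    event_probability: 10
    weights: [23, 63, 13, 0.3, 0.6]
  sga-p5:
    event_probability: 5
    weights: [16, 50, 30, 1.4, 2.6]
pairings:
  sga-threshold-shift:
    baseline: sga-p10
    intervention: sga-p5
    invasiveness: non-invasive
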