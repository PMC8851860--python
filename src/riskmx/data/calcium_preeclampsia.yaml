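# Preeclampsia risk with and without universal calcium supplementation.
# Event probabilities are population incidences in percent; weights are
# the maternal impact distribution (primary care / <2d hospital / >=2d
# hospital / serious morbidity / death) in percent of affected women,
# at full printed precision (rows sum to 100.4 and 100.42).
schema: 1
tolerance: 0.5
scenarios:
  calcium-absent:
    event_probability: 6.5
    weights: [28, 53, 15, 4.3, 0.1]
  calcium-present:
    event_probability: 4.8
    weights: [28, 54, 15, 3.4, 0.02]
pairings:
  calcium:
    baseline: calcium-absent
    intervention: calcium-present
    invasiveness: non-invasive
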