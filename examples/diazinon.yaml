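# Cholinesterase-inhibitor poisoning under a constant secretagogue drive:
# full k_cat knock-down at t = 60 min drives receptor saturation and
# sustained packaging overflow (classification: hyperstimulation).
preset: canine-default
t_span: [0, 500]
input:
  constant: 100.0
interventions:
  - {kind: diazinon, time: 60, inhibition: 1.0}
output:
  trajectory: diazinon_traj.csv
  summary: diazinon_summary.json
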