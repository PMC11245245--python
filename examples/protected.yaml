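# Receptor blockade immediately before the cholinesterase inhibitor:
# synthesis stops at the block, so no overflow develops even though BCHE
# activity is destroyed (classification: none).
preset: canine-default
t_span: [0, 500]
input:
  constant: 100.0
interventions:
  - {kind: atropine, time: 59, block: 1.0}
  - {kind: diazinon, time: 60, inhibition: 1.0}
output:
  trajectory: protected_traj.csv
  summary: protected_summary.json
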