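# A single 2-hour meal with 5-minute on/off ramps; after the vagal drive
# ceases the residual interstitial BCHE clears the remaining ACh and the
# pancreas returns to rest.
preset: canine-default
t_span: [0, 500]
input:
  meals:
    - {start: 0, duration: 120, amplitude: 100}
  ramp: 5.0
output:
  trajectory: meal_traj.csv
  summary: meal_summary.json
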