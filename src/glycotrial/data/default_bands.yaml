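# Default sliding-scale insulin band table.
#
# This is a RECONSTRUCTION of the nine-center consensus algorithm built
# around its published anchor points (infusion started at >=150 mg/dL,
# glycemic target 110-150, moderate hypoglycemia 50-80, severe <50); the
# full bedside table was only circulated as supplementary material and is
# not reproduced here.  Override any of it with --bands / load_bands().
#
# Schema: bands = list of {low, high, action, amount}; high may be .inf.
#   action: stop  -> rate 0 (pump stays armed)
#           hold  -> keep current rate
#           set   -> absolute rate, IU/h  (amount)
#           delta -> rate change, IU/h    (amount, may be negative)
#           scale -> multiply rate        (amount)
# Severe hypoglycemia (< severe_threshold) always stops AND de-arms the
# pump regardless of the table; re-arming requires restart_threshold.
start_threshold: 150
restart_threshold: 150
severe_threshold: 50
max_rate: 4.0     # IU/h ceiling of the scale; escalations saturate here
bands:
  - {low: 0,   high: 50,   action: stop}        # severe hypoglycemia
  - {low: 50,  high: 80,   action: stop}        # moderate: stop, recheck
  - {low: 80,  high: 110,  action: scale, amount: 0.5}   # below target: halve
  - {low: 110, high: 150,  action: hold}        # in target: no change
  - {low: 150, high: 200,  action: delta, amount: 0.5}
  - {low: 200, high: 250,  action: delta, amount: 1.0}
  - {low: 250, high: .inf, action: delta, amount: 2.0}
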