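# Audit of the elderly-priming walking-speed claim.
# The Bayes factor is stipulated at its published value (BF10 = 3) so the
# audit reproduces the printed numbers exactly; the study row lets the
# `bf` recompute mode show what each translation method would give.
claim:
  text: "Exposure to elderly-related words causes slower walking speed."
  strength: strong_causal_general
  scope_note: "causal and general; extends beyond the tested conditions"
priors:
  - value: 0.05
    label: skeptical
  - value: 0.10
    label: moderate
  - value: 0.20
    label: optimistic
evidence:
  stipulated: [3.0]
  studies:
    - label: "original elderly-priming study"
      t: 2.0
      df: 28
      n1: 15
      n2: 15
      p: 0.05
      d: 0.75
      direction: predicted_positive
  method:
    method: jzs
    prior_scale: 0.7071067811865476
    sided: two_sided
  combine: false
sensitivity:
  bfs: [1.0, 3.0, 10.0]
  reasonable_band: [0.05, 0.20]
  threshold: 0.5
  grid_points: 99
output:
  formats: [markdown, json]
seed: 0
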