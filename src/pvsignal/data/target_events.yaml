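# Named target adverse-event sets (name -> list of MedDRA-style PTs).
# The default study target is the single preferred term OSTEOPENIA; the
# broader bone-loss set is provided for sensitivity analyses.
osteopenia:
  - OSTEOPENIA
bone_loss_broad:
  - OSTEOPENIA
  - OSTEOPOROSIS
  - BONE DENSITY DECREASED
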