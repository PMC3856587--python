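# The four simulation scenarios: every node starts active (1) except the
# stress and SSRI inputs, which are permuted on/off.  TRP starts active and,
# like stress and SSRI, is clamped for the whole run.
scenarios:
  basal:          {stress: 0, ssri: 0}
  antidepressant: {stress: 0, ssri: 1}
  chronic_stress: {stress: 1, ssri: 0}
  complete:       {stress: 1, ssri: 1}
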