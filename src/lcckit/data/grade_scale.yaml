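# Five-class grading standard for the integrated land-carrying-capacity
# score on [0, 1].  Bins are closed below and open above; the top bin is
# closed at 1.
bins:
  - {lower: 0.0, upper: 0.2, label: Weakest}
  - {lower: 0.2, upper: 0.4, label: Weak}
  - {lower: 0.4, upper: 0.6, label: Medium}
  - {lower: 0.6, upper: 0.8, label: Strong}
  - {lower: 0.8, upper: 1.0, label: Strongest}
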