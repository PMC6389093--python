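# Cumulative recurrent-stroke risk anchors per ABCD2 band:
# stratum -> list of [horizon_days, cumulative_risk].
# Replace with your preferred literature values.
HIGH:
- - 2
  - 0.081
- - 7
  - 0.117
- - 90
  - 0.178
LOW:
- - 2
  - 0.01
- - 7
  - 0.012
- - 90
  - 0.031
MODERATE:
- - 2
  - 0.041
- - 7
  - 0.059
- - 90
  - 0.098
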