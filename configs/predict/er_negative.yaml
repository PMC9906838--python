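er_stratum: negative
covariate_terms:
- name: age
  coefficient: 0.008
  transform: identity
  centre: 61.8
- name: size_mm
  coefficient: 0.4
  transform: log
  centre: 3.1354942159291497
- name: nodes
  coefficient: 0.45
  transform: log1p
  centre: 0.0
- name: grade_2
  coefficient: 0.35
  transform: identity
  centre: 0.0
- name: grade_3
  coefficient: 0.7
  transform: identity
  centre: 0.0
- name: her2_pos
  coefficient: 0.25
  transform: identity
  centre: 0.0
- name: detection_symptomatic
  coefficient: 0.15
  transform: identity
  centre: 0.0
treatment_log_hrs:
  hormone: 0.0
  chemo_second: -0.302
  chemo_third: -0.501
  trastuzumab: -0.357
baseline_survival:
  times:
  - 0.0
  - 1.0
  - 2.0
  - 3.0
  - 4.0
  - 5.0
  - 6.0
  - 7.0
  - 8.0
  - 9.0
  - 10.0
  - 11.0
  - 12.0
  - 13.0
  - 14.0
  - 15.0
  survival:
  - 1.0
  - 0.955997
  - 0.916737
  - 0.880043
  - 0.8454
  - 0.812529
  - 0.781248
  - 0.751416
  - 0.722925
  - 0.695682
  - 0.669608
  - 0.644634
  - 0.6207
  - 0.597747
  - 0.575727
  - 0.554593
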