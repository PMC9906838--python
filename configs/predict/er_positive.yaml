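er_stratum: positive
covariate_terms:
- name: age
  coefficient: 0.012
  transform: identity
  centre: 61.8
- name: size_mm
  coefficient: 0.45
  transform: log
  centre: 3.1354942159291497
- name: nodes
  coefficient: 0.5
  transform: log1p
  centre: 0.0
- name: grade_2
  coefficient: 0.45
  transform: identity
  centre: 0.0
- name: grade_3
  coefficient: 0.9
  transform: identity
  centre: 0.0
- name: her2_pos
  coefficient: 0.3
  transform: identity
  centre: 0.0
- name: ki67_pos
  coefficient: 0.25
  transform: identity
  centre: 0.0
- name: detection_symptomatic
  coefficient: 0.2
  transform: identity
  centre: 0.0
treatment_log_hrs:
  hormone: -0.386
  chemo_second: -0.248
  chemo_third: -0.446
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
  - 0.984127
  - 0.966285
  - 0.947836
  - 0.929121
  - 0.910311
  - 0.89151
  - 0.872791
  - 0.854203
  - 0.835784
  - 0.817562
  - 0.799561
  - 0.781796
  - 0.764283
  - 0.747031
  - 0.730048
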