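name: odx_like
archetype: linear
offset: 0.0
gene_weights:
  SIG001: 0.5818688179737357
  SIG002: 0.6534066717678023
  SIG003: 1.0378923658661874
  SIG004: 0.9410037366007796
  SIG005: 0.7128876404815272
  SIG006: 0.6662511422931077
  SIG007: 0.8786470028697518
  SIG008: 0.5493873484829707
  SIG009: 0.9382048352116971
  SIG010: 1.1534422922159497
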