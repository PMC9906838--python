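name: mammaprint_like
archetype: template
offset: 0.0
template_vector:
  SIG001: -1.0
  SIG002: -1.0
  SIG003: -1.0
  SIG004: -1.0
  SIG005: -1.0
  SIG006: -1.0
  SIG007: -1.0
  SIG008: -1.0
  SIG009: -1.0
  SIG010: -1.0
  SIG011: 1.0
  SIG012: 1.0
  SIG013: 1.0
  SIG014: 1.0
  SIG015: 1.0
  SIG016: 1.0
  SIG017: 1.0
  SIG018: 1.0
  SIG019: 1.0
  SIG020: 1.0
correlation: pearson
risk_threshold: 0.0
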