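name: prosigna_c_like
archetype: centroid
offset: 0.0
centroid_matrix:
  basal_like:
    SIG001: 1.0
    SIG002: 1.0
    SIG003: 1.0
    SIG004: 1.0
    SIG005: 1.0
    SIG006: 1.0
    SIG007: 1.0
    SIG008: 1.0
    SIG009: 1.0
    SIG010: 1.0
    SIG011: -1.0
    SIG012: -1.0
    SIG013: -1.0
    SIG014: -1.0
    SIG015: -1.0
    SIG016: -1.0
    SIG017: -1.0
    SIG018: -1.0
    SIG019: -1.0
    SIG020: -1.0
  luminal_a:
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
class_weights:
  basal_like: 0.5
  luminal_a: -0.5
clinical_terms:
  size_mm: 0.005
correlation: spearman
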