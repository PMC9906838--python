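name: endopredict_like
archetype: linear
offset: 5.0
gene_weights:
  SIG005: 0.47377200024069965
  SIG006: 0.9642168062833227
  SIG007: 0.7670662171702607
  SIG008: 0.3671285549158784
  SIG009: 0.609287766317469
  SIG010: 0.9205359435292624
  SIG011: -0.7882174499174155
  SIG012: -0.5285310048490784
  SIG013: -0.8137497143310466
  SIG014: -0.45409446888184035
  SIG015: -0.3571161986795457
  SIG016: -0.41192692075253323
scale_bounds:
- 0.0
- 15.0
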