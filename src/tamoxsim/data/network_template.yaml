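# Template metabolic network: base rate constants (1/h) on the EM scale,
# CYP2D6 fractions per edge, apparent volumes (L) and oral absorption.
edges:
- source: TAM
  target: NDM
  rate_per_h: 0.003300700859809264
  cyp2d6_fraction: 0.0
- source: TAM
  target: 4OH
  rate_per_h: 0.00016503504299046317
  cyp2d6_fraction: 0.5
- source: TAM
  target: sink
  rate_per_h: 0.0006601401719618527
  cyp2d6_fraction: 0.0
- source: NDM
  target: END
  rate_per_h: 0.0001604507362407281
  cyp2d6_fraction: 0.95
- source: NDM
  target: sink
  rate_per_h: 0.0014440566261665528
  cyp2d6_fraction: 0.0
- source: 4OH
  target: END
  rate_per_h: 0.004332169878499658
  cyp2d6_fraction: 0.0
- source: 4OH
  target: sink
  rate_per_h: 0.010108396383165867
  cyp2d6_fraction: 0.0
- source: END
  target: sink
  rate_per_h: 0.011552453009332421
  cyp2d6_fraction: 0.0
volumes_L:
  TAM: 1000.0
  NDM: 1000.0
  4OH: 300.0
  END: 150.0
absorption:
  TAM:
    ka_per_h: 0.23104906018664842
    bioavailability: 0.6
  END:
    ka_per_h: 0.23104906018664842
    bioavailability: 0.3
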