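# Van der Waals radii (Angstrom), Bondi, J. Phys. Chem. 68:441 (1964).
# P from the same compilation; hydrogens are assigned radius 0.0 by
# assign_radii (they are excluded from grid occupancy), so the H entry
# here is only used when a caller explicitly requests it.
name: bondi_1964
radii:
  H: 1.20
  C: 1.70
  N: 1.55
  O: 1.52
  S: 1.80
  P: 1.80
  F: 1.47
  CL: 1.75
  BR: 1.85
  I: 1.98
  SE: 1.90
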