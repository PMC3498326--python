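# Default run configuration. The three distance criteria and sigma0_sq are
# NON-CANONICAL defaults: the original values are configuration of the method,
# not constants of the package. Override them per run.
distance_cutoffs:
  hbond: 3.3        # A, alleged H-bonds and charged groups (non-canonical default)
  dispersion: 4.0   # A, probable dispersion contacts (non-canonical default)
  halogen: 3.6      # A, halogen bonds (non-canonical default)
prior:
  sigma0_sq: 0.04   # A^2, fixed prior variance constant (non-canonical default)
density:
  min_modes: 1
  max_modes: 4
  var_floor: 1.0e-4
  kappa_cap: 500.0
mass:
  quadrature_order: 64
bootstrap:
  n_volumes: 1000
  rel_jitter: 0.05
  jitter_center: false
screening:
  ridge: 1.0e-4
simulate:
  seed: 17
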