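# Mixed-bias refinement campaign on the 2D double-well: ten exploratory
# well-tempered metadynamics runs plus ten runs that additionally carry a
# harmonic restraint localized in the poorly sampled transition region.
grid:
  bounds: [[-3.0, 3.0], [-3.0, 3.0]]
  nbins: [64, 64]
potential:
  name: doublewell_2d
kT: 1.0
langevin:
  dt: 0.005
  friction: 1.0
  mass: 1.0
  nsteps: 200000
  sample_stride: 10
  initial: random
  domain_margin: 1.0
metad:
  height: 1.0
  sigma: [0.25, 0.25]
  pace: 200
  bias_factor: 10.0
kde:
  bandwidth: [0.125, 0.125]
runs: 20
seed: 2000
per_run:
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {}
  - {static_biases: [{type: harmonic, center: [0.0, 0.0], kappa: [2.0, 2.0]}]}
  - {static_biases: [{type: harmonic, center: [-0.6, 0.6], kappa: [2.0, 2.0]}]}
  - {static_biases: [{type: harmonic, center: [0.6, -0.6], kappa: [2.0, 2.0]}]}
  - {static_biases: [{type: harmonic, center: [0.0, 0.0], kappa: [2.0, 2.0]}]}
  - {static_biases: [{type: harmonic, center: [-0.6, 0.6], kappa: [2.0, 2.0]}]}
  - {static_biases: [{type: harmonic, center: [0.6, -0.6], kappa: [2.0, 2.0]}]}
  - {static_biases: [{type: harmonic, center: [0.0, 0.0], kappa: [2.0, 2.0]}]}
  - {static_biases: [{type: harmonic, center: [-0.6, 0.6], kappa: [2.0, 2.0]}]}
  - {static_biases: [{type: harmonic, center: [0.6, -0.6], kappa: [2.0, 2.0]}]}
  - {static_biases: [{type: harmonic, center: [0.0, 0.0], kappa: [2.0, 2.0]}]}
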