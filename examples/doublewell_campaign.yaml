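# Trivially parallel campaign: 20 short well-tempered metadynamics runs on
# the 2D double-well benchmark, each randomly initialized, merged into a
# single free-energy surface at analysis time.
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
volume:
  threshold_fraction: 0.01
runs: 20
seed: 1000
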