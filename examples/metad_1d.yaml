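# Single well-tempered metadynamics run on the 1D multiwell model:
# several interconverting basins below s = 0.5 and one metastable state
# near s = 0.8 discovered later in the run.
grid:
  bounds: [[-0.2, 1.2]]
  nbins: 256
potential:
  name: multiwell_1d
kT: 1.0
langevin:
  dt: 0.005
  friction: 2.0
  mass: 1.0
  nsteps: 400000
  sample_stride: 10
  initial: [0.1]
  domain_margin: 0.5
metad:
  height: 0.25
  sigma: [0.04]
  pace: 200
  bias_factor: 8.0
kde:
  bandwidth: [0.02]
runs: 1
seed: 11
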