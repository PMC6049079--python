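# Potassium diffusion with astrocyte buffering in a 1 mm^3 box of ECS.
# Run:  ecsrd simulate --config examples/potassium-buffer.yaml --out out/
seed: 1
region:
  xlo: -500
  ylo: -500
  zlo: -500
  xhi: 500
  yhi: 500
  zhi: 500
  dx: 10
  volume_fraction: 0.2
  tortuosity: 1.6
species:
  - name: k
    d: 2.62
    charge: 1
    initial: {function: sphere, inside: 40.0, outside: 3.5, radius: 100.0}
    ecs_boundary_conditions: 3.5
  - name: A
    initial: 10.0
  - name: AK
    initial: 0.0
reactions:
  - lhs: k + A
    rhs: AK
    kf: 0.0008/(1.0 + exp(-(k - 15.0)/1.15))
    kb: 0.0008
solver:
  dt: 0.1
  t_stop: 100.0
  snapshot_every: 50.0
output:
  directory: out
  formats: [nrrd, csv]
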