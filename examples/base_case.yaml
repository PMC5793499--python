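# Cylindrical finite-rate base case from dimensional (cm/g/day) inputs:
# a 1 cm Mg rod with k = 0.07 cm^4/(g day), eps1 = 0.6, eps2 = 0.4.
# Run with:  mgcorrode run --config examples/base_case.yaml
physical:
  k: 0.07
  eps1: 0.6
  eps2: 0.4
geometry: 1
initial_size: 1.0
case: 2
solver:
  n1: 100
  n2: 100
outputs:
  directory: results/base_case
  snapshot_times: [0.095, 10.0, 100.0]
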