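# Demo pipeline: simulate a single expanding radial wave, aggregate the
# surveys, compare a reduced model catalogue and render one growth field.
# Run with:  wavegam run --config examples/demo.yaml
out_dir: artefacts/demo
radius: 5000.0
quarter_length: 91.0
offset: 3.03
iterations: 1500        # reduced from the full 15,000 for a quick demo
seed: 17
models: [N1, N2, N3, P, RE, RC]
simulate:
  waves:
    - form: radial-expanding
      zeta: 500.0       # metres/day
      gamma: 70000.0    # epicentre easting, metres
      psi: 60000.0      # epicentre northing, metres
      amplitude: 1.5    # growth-rate amplitude per quarter
  period: 1095.0        # 3-year cycle, days
  sigma: 0.3
  duration: 2190.0      # six years
  design:
    mode: uniform
    n_surveys_per_quarter: 150
    seed: 5
profiles: [zeta]
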