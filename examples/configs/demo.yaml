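# End-to-end demo configuration for `cvpgrad pipeline`.
# Simulates a CVP acquisition of a trapezoid through a ringing gradient
# chain, estimates the waveform with VP and CVP, and estimates/applies a
# GSTF on the same chain model.
seed: 7
model:
  delay: 2.0                 # us
  lowpass_bandwidth: 15.0    # kHz
  resonance_terms:           # (fraction, kHz, damping ms)
    - [0.005, 1.1, 2.0]
scheme:
  method: cvp
  n_prephasers: 5
  test:
    kind: trapezoid
    amplitude: 10.0          # mT/m
    ramp_time: 150.0         # us
    flat_time: 300.0         # us
    dwell: 1.0               # us
slices:
  positions: [-20.0, -15.0, -10.0, -5.0, 0.001, 5.0, 10.0, 15.0, 20.0]  # mm
  thickness: 3.0             # mm
simulate:
  dwell: 2.0                 # us readout dwell
  readout_duration: 1500.0   # us
  noise_sigma: 0.002
  intra_slice_points: 64
estimate:
  methods: [vp, cvp]
  filter_length: 3
gstf:
  dwell: 5.0
  n_triangles: 12
  amplitude: 20.0
  regularization: 1.0e-6
  predict:
    kind: trapezoid
    amplitude: 25.0
    ramp_time: 200.0
    flat_time: 500.0
    dwell: 5.0
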