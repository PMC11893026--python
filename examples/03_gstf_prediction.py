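"""Estimate a gradient system transfer function and predict a waveform.

Probes a simulated chain with 12 triangles of staggered ramp durations,
estimates the GSTF by regularized spectral inversion, and predicts the
chain's response to an unseen trapezoid.
"""

import numpy as np

from cvpgrad import (GradientChainModel, apply_chain, estimate_gstf,
                     make_triangle_set, make_trapezoid, predict_waveform)

chain = GradientChainModel(delay=3.0, lowpass_bandwidth=20.0,
                           eddy_terms=((0.01, 1.5),),
                           resonance_terms=((0.004, 1.2, 2.5),))
triangles = make_triangle_set(12, amplitude=20.0, dwell=5.0)
measured = [apply_chain(t, chain, tail_us=4000.0) for t in triangles]
gstf = estimate_gstf(triangles, measured, regularization=1e-6)

band = np.abs(gstf.freq) < 3.0
f_peak = gstf.freq[band][np.argmax(np.abs(gstf.H[band]))]
print(f"GSTF grid: {gstf.freq.size} bins, "
      f"{gstf.freq[1] - gstf.freq[0]:.4f} kHz resolution")
print(f"|H| peaks at {abs(f_peak):.2f} kHz "
      f"(mechanical resonance set at 1.20 kHz)")
print(f"Hermitian symmetry residual: {gstf.hermitian_error():.2e}")

trapezoid = make_trapezoid(25.0, 200.0, 500.0, dwell=5.0)
predicted = predict_waveform(trapezoid, gstf)
truth = apply_chain(trapezoid, chain, tail_us=float(trapezoid.duration))
n = min(predicted.samples.size, truth.samples.size)
err = 100.0 * np.abs(predicted.samples[:n] - truth.samples[:n]).max() \
    / np.abs(truth.samples).max()
print(f"prediction error on an unseen 25 mT/m trapezoid: {err:.2f}% of peak")
print("\nThe prediction reproduces delay, droop and ringing of the chain "
      "because all of\nthem are linear time-invariant effects the GSTF "
      "captures.")
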