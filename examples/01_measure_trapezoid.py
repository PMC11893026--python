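"""Measure a trapezoidal test gradient with VP and CVP.

Builds a 10 mT/m trapezoid (150 us ramps, 300 us flat top), sends it through
a simulated gradient chain with a mechanical resonance, acquires the
four-step CVP FID dataset over 9 slices, and recovers the waveform with both
the VP equations (steps 1-2 only) and the full CVP system.
"""

import numpy as np

from cvpgrad import (GradientChainModel, SliceSet, build_scheme,
                     choose_prephasers, estimate_waveform, make_slice_select,
                     make_trapezoid, simulate_fid, simulated_test_gradient)

test = make_trapezoid(10.0, 150.0, 300.0, dwell=1.0)
slice_select, excitation = make_slice_select(6.0, 100.0, 300.0, dwell=1.0)
amplitudes = choose_prephasers(test, 5)
scheme = build_scheme("cvp", test, amplitudes, slice_select, excitation,
                      readout_duration=1500.0)
chain = GradientChainModel(delay=2.0, lowpass_bandwidth=15.0,
                           resonance_terms=((0.005, 1.1, 2.0),))
slices = SliceSet(np.linspace(-20.0, 20.0, 9), thickness=3.0)

data = simulate_fid(scheme, chain, slices, dwell=2.0)
truth = simulated_test_gradient(scheme, chain, dwell=2.0)
peak = np.abs(truth).max()

print(f"prephaser amplitudes (mT/m): {np.round(amplitudes, 2)}")
for method in ("vp", "cvp"):
    g = estimate_waveform(data, method).g
    err = 100.0 * np.nanmax(np.abs(g - truth)[2:-2]) / peak
    print(f"{method:>4}: max |G_hat - G_true| = {err:.3f}% of the "
          f"{peak:.1f} mT/m peak")

print("\nThe CVP error stays at the discretization floor; the VP error is "
      "larger because\nthe lingering resonance of the strongest prephaser "
      "leaks into its solution.")
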