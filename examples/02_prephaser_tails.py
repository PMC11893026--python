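"""Explain the VP-CVP difference as weighted prephaser lingering fields.

The VP solution weights each prephasing step by its squared signal
magnitude.  Because the strongest prephaser rephases the signal late, its
lingering oscillations dominate the VP estimate after the test gradient
ends.  This script reproduces that diagnosis: the VP-CVP difference matches
the |S|^2-weighted sum of the simulated prephaser tails.
"""

import numpy as np

from cvpgrad import (GradientChainModel, SliceSet, build_scheme,
                     choose_prephasers, estimate_waveform, make_slice_select,
                     make_trapezoid, prephaser_outputs, simulate_fid,
                     vp_tail_prediction)

test = make_trapezoid(10.0, 150.0, 300.0, dwell=1.0)
ss, exc = make_slice_select(6.0, 100.0, 300.0, dwell=1.0)
scheme = build_scheme("cvp", test, choose_prephasers(test, 5), ss, exc,
                      readout_duration=1500.0)
chain = GradientChainModel(delay=2.0, lowpass_bandwidth=15.0,
                           resonance_terms=((0.005, 1.1, 2.0),))
data = simulate_fid(scheme, chain, SliceSet(np.linspace(-20, 20, 9), 3.0),
                    dwell=2.0)

difference = estimate_waveform(data, "vp").g - estimate_waveform(data, "cvp").g
tails = prephaser_outputs(scheme, chain, dwell=2.0)
prediction = vp_tail_prediction(data, tails)

t = data.times - scheme.readout_start
after = t > 650.0  # after the test gradient switches off
r_all = np.corrcoef(difference[2:-2], prediction[2:-2])[0, 1]
r_tail = np.corrcoef(difference[after], prediction[after])[0, 1]
print(f"corr(VP - CVP, weighted prephaser tails), full readout : {r_all:.4f}")
print(f"corr(VP - CVP, weighted prephaser tails), after the test: {r_tail:.4f}")
print(f"largest tail amplitude entering the readout: "
      f"{np.abs(tails).max() * 1e3:.1f} uT/m")
print("\nA correlation near 1 shows the VP bias is exactly the "
      "magnitude-weighted\ncombination of the uncompensated prephaser "
      "lingering fields.")
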