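"""EPI Nyquist-ghost suppression by trajectory correction.

Simulates a 64x64 single-shot EPI acquisition through a gradient chain with
a mechanical resonance near the readout frequency, then reconstructs the
image three ways: navigator-corrected with the nominal trajectory,
GSTF-predicted trajectory, and the true (simulated) trajectory.  The
relative ghost intensity Gamma quantifies the residual N/2 ghost.
"""

import warnings

import numpy as np

from cvpgrad import (GradientChainModel, apply_chain, estimate_gstf,
                     make_triangle_set, predict_waveform)
from cvpgrad.epi import (design_epi, ghost_intensity, integrate_trajectory,
                         make_phantom, navigator_correct, reconstruct,
                         simulate_epi_raw)

geo = design_epi(matrix_size=64, fov_mm=200.0, dwell_adc=5.0)
chain = GradientChainModel(delay=3.0, lowpass_bandwidth=30.0,
                           resonance_terms=((0.004, 1.0, 3.0),),
                           sign_asymmetry=0.002)
actual = apply_chain(geo.readout, chain, tail_us=1000.0)
traj_true = integrate_trajectory(actual, geo.adc_times, k_pe=geo.k_pe,
                                 nominal=geo.readout)
traj_nominal = integrate_trajectory(geo.readout, geo.adc_times, k_pe=geo.k_pe)

triangles = make_triangle_set(12, 20.0, 5.0)
gstf = estimate_gstf(triangles,
                     [apply_chain(t, chain, tail_us=3000.0) for t in triangles])
traj_gstf = integrate_trajectory(predict_waveform(geo.readout, gstf),
                                 geo.adc_times, k_pe=geo.k_pe,
                                 nominal=geo.readout)

refs = integrate_trajectory(actual, geo.adc_times[:3], k_pe=np.zeros(3),
                            nominal=geo.readout)
raw = simulate_epi_raw(make_phantom(64), traj_true, 200.0, ref_traj=refs,
                       dwell_adc=5.0)

shifts = traj_true.echo_center_k[:6]
print("echo-center k_RO of the first lines (1/m):", np.round(shifts, 2))
print("-> odd/even centers are shifted against each other and oscillate.\n")

roi1 = (1, 24, 5, 16)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for name, image in [
            ("navigator + nominal trajectory",
             reconstruct(navigator_correct(raw), traj_nominal)),
            ("GSTF-predicted trajectory", reconstruct(raw, traj_gstf)),
            ("true-waveform trajectory", reconstruct(raw, traj_true))]:
        print(f"Gamma = {ghost_intensity(image, roi1).gamma:6.2f}%   {name}")

print("\nGamma is the peak ghost intensity relative to the object signal in "
      "the same\nregion shifted by FOV/2: the measured-trajectory "
      "reconstruction suppresses the\nghost best, the GSTF prediction "
      "misses only the (nonlinear) amplifier asymmetry.")
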